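"""Plain-text table I/O: epitope annotations, server rankings, predictions."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .meta import ServerRanking
from .structure import ResidueId


def _rid_columns(df: pd.DataFrame) -> list[ResidueId]:
    icodes = df.get("icode")
    if icodes is None:
        icodes = [""] * len(df)
    else:
        icodes = ["" if pd.isna(v) or str(v) in ("", "nan") else str(v)
                  for v in icodes]
    return [ResidueId(str(c), int(n), ic)
            for c, n, ic in zip(df["chain"], df["resnum"], icodes)]


def read_epitope_annotation(path) -> set[ResidueId]:
    """TSV with columns chain, resnum, icode (icode may be blank)."""
    df = pd.read_csv(path, sep="\t", dtype={"chain": str})
    return set(_rid_columns(df))


def write_epitope_annotation(epitope: set[ResidueId], path) -> None:
    rows = [{"chain": r.chain, "resnum": r.resnum, "icode": r.icode}
            for r in sorted(epitope)]
    pd.DataFrame(rows, columns=["chain", "resnum", "icode"]).to_csv(
        path, sep="\t", index=False)


def read_server_rankings(path) -> dict[str, ServerRanking]:
    """TSV with columns server, chain, resnum, icode, score; residues are
    ranked per server by decreasing score."""
    df = pd.read_csv(path, sep="\t", dtype={"chain": str, "server": str})
    rankings = {}
    for server, group in df.groupby("server", sort=False):
        rids = _rid_columns(group)
        scores = dict(zip(rids, group["score"].astype(float)))
        rankings[str(server)] = ServerRanking.from_scores(str(server), scores)
    return rankings


def write_server_rankings(rankings: Mapping[str, ServerRanking], path) -> None:
    rows = []
    for name, ranking in rankings.items():
        n = len(ranking.order)
        for i, rid in enumerate(ranking.order):
            rows.append({"server": name, "chain": rid.chain,
                         "resnum": rid.resnum, "icode": rid.icode,
                         "score": (n - i) / n})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_residue_scores(table, path, predicted: set[ResidueId] | None = None,
                         ) -> None:
    df = table.table.copy()
    df[["chain", "resnum", "icode"]] = pd.DataFrame(
        [[r.chain, r.resnum, r.icode] for r in df["residue"]])
    df = df[["chain", "resnum", "icode", "score", "n_patches", "rank"]]
    if predicted is not None:
        df["predicted_epitopic"] = [
            ResidueId(c, n, i) in predicted
            for c, n, i in zip(df["chain"], df["resnum"], df["icode"])]
    df.to_csv(path, sep="\t", index=False)


def write_corpus(corpus, out_dir) -> None:
    """Materialise a synthetic corpus: per target a PDB file, an epitope
    annotation and one PSSM file per chain."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for target in corpus:
        (out / f"{target.target_id}.pdb").write_text(target.fixture.pdb_text)
        write_epitope_annotation(target.epitope,
                                 out / f"{target.target_id}.epitope.tsv")
        for chain, text in target.pssm_texts.items():
            (out / f"{target.target_id}.pssm.{chain}.txt").write_text(text)


def read_corpus_dir(data_dir):
    """Load the layout written by ``write_corpus``: yields
    (target_id, pdb_text, epitope set, {chain: pssm text})."""
    data = Path(data_dir)
    for pdb_path in sorted(data.glob("*.pdb")):
        target_id = pdb_path.stem
        epitope_path = data / f"{target_id}.epitope.tsv"
        epitope = (read_epitope_annotation(epitope_path)
                   if epitope_path.exists() else set())
        pssms = {}
        for pssm_path in sorted(data.glob(f"{target_id}.pssm.*.txt")):
            chain = pssm_path.name.split(".")[-2]
            pssms[chain] = pssm_path.read_text()
        yield target_id, pdb_path.read_text(), epitope, pssms
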
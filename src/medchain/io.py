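"""Readers and writers for the package's plain-text data dialects.

All artifacts are TSV/CSV/JSON so that synthetic datasets, intermediate
stage outputs and reports remain inspectable and diffable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mr import InstrumentTable
from .synth import Cohort, TruthRecord


def write_gwas(tables: dict[str, InstrumentTable], outdir: str | Path) -> None:
    """Write stacked summary statistics and per-gene LD matrices."""
    outdir = Path(outdir)
    (outdir / "ld").mkdir(parents=True, exist_ok=True)
    stacked = []
    for gene, t in tables.items():
        df = t.snps.copy()
        df.insert(1, "gene", gene)
        stacked.append(df)
        ld = pd.DataFrame(t.ld_r2, index=t.snps["snp"], columns=t.snps["snp"])
        ld.to_csv(outdir / "ld" / f"{gene}.tsv", sep="\t")
    pd.concat(stacked, ignore_index=True).to_csv(outdir / "gwas_summary.tsv", sep="\t", index=False)


def read_gwas(indir: str | Path) -> dict[str, InstrumentTable]:
    indir = Path(indir)
    stacked = pd.read_csv(indir / "gwas_summary.tsv", sep="\t")
    tables = {}
    for gene, sub in stacked.groupby("gene", sort=False):
        ld = pd.read_csv(indir / "ld" / f"{gene}.tsv", sep="\t", index_col=0)
        tables[gene] = InstrumentTable(
            snps=sub.drop(columns="gene").reset_index(drop=True),
            ld_r2=ld.to_numpy(),
            gene=str(gene),
        )
    return tables


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.data.to_csv(outdir / "cohort.csv", index=False)
    cohort.expression.to_csv(outdir / "expression.tsv", sep="\t")
    cohort.methylation.to_csv(outdir / "methylation.tsv", sep="\t")
    cohort.annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)


def read_cohort(indir: str | Path) -> Cohort:
    indir = Path(indir)
    expr = pd.read_csv(indir / "expression.tsv", sep="\t", index_col=0)
    meth = pd.read_csv(indir / "methylation.tsv", sep="\t", index_col=0)
    expr.columns = range(expr.shape[1])
    meth.columns = range(meth.shape[1])
    return Cohort(
        data=pd.read_csv(indir / "cohort.csv"),
        expression=expr,
        methylation=meth,
        annotation=pd.read_csv(indir / "annotation.tsv", sep="\t"),
    )


def write_truth(truth: TruthRecord, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True))


def read_truth(path: str | Path) -> TruthRecord:
    return TruthRecord(**json.loads(Path(path).read_text()))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True))
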
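"""Table I/O for the polysome-loading pipeline.

Every table the pipeline touches is a tab-separated UTF-8 file with a '.'
decimal separator and no quoting, so that identical inputs produce
byte-identical outputs.  Parsers validate strictly and raise rather than
coerce: an unknown fraction label, a negative count, or a ragged row is an
error, never a silently filled NA.

Genomic DNA allele counts travel in the same schema as RNA counts, encoded
under the pseudo-fraction label ``GDNA``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "FRACTIONS",
    "GDNA",
    "RNA_CLASSES",
    "SchemaError",
    "TableParseError",
    "ExpressionMatrix",
    "read_allele_count_table",
    "write_allele_count_table",
    "read_expression_table",
    "write_expression_table",
    "read_mirna_count_table",
    "read_target_map",
    "read_vcf_het_sites",
    "write_results",
]

#: Sucrose-gradient fraction labels. POLYSOME denotes pooled fractions with
#: three or more ribosomes per transcript.
FRACTIONS = ("CYTOSOL", "MONOSOME", "LIGHT", "INTERMEDIATE", "HEAVY", "POLYSOME")

#: Pseudo-fraction under which genomic-DNA allele counts are stored.
GDNA = "GDNA"

#: Fixed RNA-class vocabulary for expression tables.
RNA_CLASSES = (
    "protein_coding",
    "pseudogene",
    "lncRNA_antisense",
    "lincRNA",
    "lncRNA_other",
    "microRNA",
    "other",
)

_ALLELE_COLUMNS = ["sample_id", "fraction", "gene_id", "snp_id", "ref_count", "alt_count"]
_FEATURE_COLUMNS = ["feature_id", "gene_id", "rna_class", "length_bases"]


class SchemaError(ValueError):
    """A table's header or vocabulary does not match the declared schema."""


class TableParseError(ValueError):
    """A table row violates an invariant (type, sign, uniqueness)."""


@dataclass
class ExpressionMatrix:
    """Feature-level count matrix with feature metadata.

    ``features`` is indexed by feature_id with columns gene_id, rna_class and
    length_bases; ``counts`` shares the index and has a (sample_id, fraction)
    MultiIndex on its columns.
    """

    features: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.counts.index):
            raise SchemaError("feature metadata and counts must share one feature index")
        if (self.features["length_bases"] <= 0).any():
            bad = self.features.index[self.features["length_bases"] <= 0][0]
            raise TableParseError(f"feature {bad!r} has non-positive length")
        bad_class = set(self.features["rna_class"]) - set(RNA_CLASSES)
        if bad_class:
            raise SchemaError(f"unknown rna_class values: {sorted(bad_class)}")
        if (self.counts.to_numpy() < 0).any():
            raise TableParseError("negative counts in expression matrix")

    @property
    def samples(self) -> list[str]:
        return sorted({s for s, _ in self.counts.columns})

    @property
    def fractions(self) -> list[str]:
        return sorted({f for _, f in self.counts.columns})

    def subset_class(self, rna_class: str) -> "ExpressionMatrix":
        keep = self.features.index[self.features["rna_class"] == rna_class]
        return ExpressionMatrix(self.features.loc[keep], self.counts.loc[keep])

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.features.equals(other.features) and self.counts.equals(other.counts)


def _require_columns(found: Iterable[str], required: Iterable[str], path: Path) -> None:
    missing = [c for c in required if c not in set(found)]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _parse_count(value: str, column: str, row: int, path: Path) -> int:
    try:
        n = int(value)
    except (TypeError, ValueError):
        raise TableParseError(
            f"{path}: row {row}: {column} {value!r} is not an integer"
        ) from None
    if n < 0:
        raise TableParseError(f"{path}: row {row}: {column} {n} is negative")
    return n


def read_allele_count_table(path: str | Path) -> pd.DataFrame:
    """Read reference/alternative allele read counts at heterozygous SNPs.

    Returns a DataFrame with columns sample_id, fraction, gene_id, snp_id,
    ref_count, alt_count.  Fractions must come from :data:`FRACTIONS` or be
    the :data:`GDNA` marker; (sample_id, fraction, snp_id) must be unique.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df.columns, _ALLELE_COLUMNS, path)
    df = df[_ALLELE_COLUMNS].copy()
    allowed = set(FRACTIONS) | {GDNA}
    bad = df.loc[~df["fraction"].isin(allowed), "fraction"]
    if len(bad):
        raise SchemaError(
            f"{path}: unknown fraction label {bad.iloc[0]!r} "
            f"(allowed: {sorted(allowed)})"
        )
    for col in ("ref_count", "alt_count"):
        df[col] = [
            _parse_count(v, col, i + 2, path)  # +2: header line is row 1
            for i, v in enumerate(df[col])
        ]
    dup = df.duplicated(subset=["sample_id", "fraction", "snp_id"])
    if dup.any():
        key = df.loc[dup, ["sample_id", "fraction", "snp_id"]].iloc[0].tolist()
        raise TableParseError(f"{path}: duplicate (sample, fraction, snp) entry {key}")
    return df


def write_allele_count_table(df: pd.DataFrame, path: str | Path) -> None:
    df = df[_ALLELE_COLUMNS]
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _split_count_column(name: str, path: Path) -> tuple[str, str]:
    if ":" not in name:
        raise SchemaError(
            f"{path}: count column {name!r} is not of the form 'sample:fraction'"
        )
    sample, fraction = name.split(":", 1)
    if fraction not in set(FRACTIONS):
        raise SchemaError(f"{path}: unknown fraction label {fraction!r} in column {name!r}")
    return sample, fraction


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a feature x (sample, fraction) count table.

    The header carries the four metadata columns of ``_FEATURE_COLUMNS``
    followed by one ``sample:fraction`` count column per library.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df.columns, _FEATURE_COLUMNS, path)
    count_cols = [c for c in df.columns if c not in _FEATURE_COLUMNS]
    if not count_cols:
        raise SchemaError(f"{path}: no 'sample:fraction' count columns found")
    pairs = [_split_count_column(c, path) for c in count_cols]
    if df["feature_id"].duplicated().any():
        dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise TableParseError(f"{path}: duplicate feature_id {dup!r}")

    features = df[_FEATURE_COLUMNS].set_index("feature_id")
    features["length_bases"] = [
        _parse_count(v, "length_bases", i + 2, path)
        for i, v in enumerate(features["length_bases"])
    ]
    counts = pd.DataFrame(index=features.index)
    for col, pair in zip(count_cols, pairs):
        try:
            counts[pair] = pd.to_numeric(df[col].to_numpy(), errors="raise")
        except (TypeError, ValueError):
            raise TableParseError(f"{path}: non-numeric count in column {col!r}") from None
    counts.columns = pd.MultiIndex.from_tuples(counts.columns, names=["sample_id", "fraction"])
    return ExpressionMatrix(features, counts)


def write_expression_table(expr: ExpressionMatrix, path: str | Path) -> None:
    out = expr.features.reset_index()
    counts = expr.counts
    for sample, fraction in counts.columns:
        out[f"{sample}:{fraction}"] = counts[(sample, fraction)].to_numpy()
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_mirna_count_table(path: str | Path) -> pd.DataFrame:
    """Read a microRNA x (sample, fraction) count table.

    Header: ``mir_id`` followed by ``sample:fraction`` columns.  Returns a
    DataFrame indexed by mir_id with a (sample_id, fraction) column
    MultiIndex.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df.columns, ["mir_id"], path)
    count_cols = [c for c in df.columns if c != "mir_id"]
    if not count_cols:
        raise SchemaError(f"{path}: no 'sample:fraction' count columns found")
    pairs = [_split_count_column(c, path) for c in count_cols]
    out = df[["mir_id"]].set_index("mir_id")
    if out.index.duplicated().any():
        raise TableParseError(f"{path}: duplicate mir_id")
    res = pd.DataFrame(index=out.index)
    for col, pair in zip(count_cols, pairs):
        res[pair] = [_parse_count(v, col, i + 2, path) for i, v in enumerate(df[col])]
    res.columns = pd.MultiIndex.from_tuples(res.columns, names=["sample_id", "fraction"])
    return res


def write_mirna_count_table(df: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(index=df.index)
    for sample, fraction in df.columns:
        out[f"{sample}:{fraction}"] = df[(sample, fraction)].to_numpy()
    out.reset_index().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_target_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column microRNA -> target-gene mapping (mir_id, gene_id)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df.columns, ["mir_id", "gene_id"], path)
    out: dict[str, set[str]] = {}
    for mir, gene in zip(df["mir_id"], df["gene_id"]):
        out.setdefault(mir, set()).add(gene)
    return out


def read_vcf_het_sites(path: str | Path) -> pd.DataFrame:
    """Extract heterozygous sites (CHROM, POS, ID) from a VCF.

    Only the genotype of the first sample is inspected; genotype likelihoods
    are ignored.  Sites with a heterozygous GT (e.g. 0/1, 0|1) are returned.
    """
    from cyvcf2 import VCF

    rows = []
    for variant in VCF(str(path)):
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        if len(variant.gt_types) and variant.gt_types[0] == 1:
            rows.append((variant.CHROM, variant.POS, variant.ID or "."))
    return pd.DataFrame(rows, columns=["chrom", "pos", "snp_id"])


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    tree_newick: str | None = None,
    summary: Mapping | None = None,
) -> list[Path]:
    """Write one TSV per named table, plus summary.json and tree.nwk.

    Rows are sorted by the table's leading column(s) and columns keep their
    given order, so two runs on identical inputs are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in sorted(tables):
        df = tables[name]
        if len(df.columns):
            df = df.sort_values(by=list(df.columns[: min(2, len(df.columns))]), kind="mergesort")
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, lineterminator="\n")
        written.append(p)
    if tree_newick is not None:
        p = out_dir / "tree.nwk"
        p.write_text(tree_newick if tree_newick.endswith("\n") else tree_newick + "\n")
        written.append(p)
    if summary is not None:
        p = out_dir / "summary.json"
        p.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        written.append(p)
    return written
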
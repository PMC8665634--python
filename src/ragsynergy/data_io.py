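"""Readers and writers for the external formats the pipeline touches.

Formats: counts TSV (genes x samples), sample sheet CSV, GFF3 gene models,
two-column TSV maps (gene -> GO terms, gene -> TF family, gene -> homolog),
and TF interaction edge lists.  All coordinates are 1-based inclusive
(GFF3 convention).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ["sample", "genotype", "treatment", "timepoint", "replicate"]


class FormatError(ValueError):
    """Malformed input file (non-integer counts, bad GFF3 line, ...)."""


class MetadataError(ValueError):
    """Counts and sample sheet disagree about the sample set."""


@dataclass
class CountMatrix:
    """Gene x sample integer counts plus per-sample metadata.

    ``library_sizes`` are the raw column sums of ``counts`` and are *not*
    recomputed when genes are filtered out downstream.
    """

    counts: pd.DataFrame  # genes x samples, integer dtype
    samples: pd.DataFrame  # indexed by sample id; genotype/treatment/timepoint/replicate
    library_sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene IDs in count matrix: {dupes[:5]}")
        if self.counts.columns.duplicated().any():
            raise FormatError("duplicate sample IDs in count matrix")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise FormatError("count matrix contains non-integer entries")
            self.counts = self.counts.round().astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise FormatError("count matrix contains negative entries")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise MetadataError(
                f"samples in count matrix missing from sample sheet: {sorted(missing)}"
            )
        # order samples as in the sheet, restricted to columns present
        order = [s for s in self.samples.index if s in set(self.counts.columns)]
        extra = set(self.samples.index) - set(self.counts.columns)
        if extra:
            raise MetadataError(
                f"samples in sheet missing from count matrix: {sorted(extra)}"
            )
        self.counts = self.counts[order]
        self.samples = self.samples.loc[order]
        self.counts.index.name = "gene"
        self.counts.columns.name = "sample"
        self.samples.index.name = "sample"
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        self.library_sizes = self.library_sizes.loc[order].astype(float)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, mask: pd.Series) -> "CountMatrix":
        """Restrict to samples where ``mask`` (indexed like samples) is True."""
        keep = self.samples.index[mask.loc[self.samples.index]]
        return CountMatrix(
            counts=self.counts[keep].copy(),
            samples=self.samples.loc[keep].copy(),
            library_sizes=self.library_sizes.loc[keep].copy(),
        )

    def subset_genes(self, genes) -> "CountMatrix":
        """Restrict to the given genes; library sizes keep pre-filter sums."""
        return CountMatrix(
            counts=self.counts.loc[genes].copy(),
            samples=self.samples.copy(),
            library_sizes=self.library_sizes.copy(),
        )

    def group_key(self) -> pd.Series:
        """(genotype, treatment, timepoint) cell label per sample."""
        s = self.samples
        return (
            s["genotype"].astype(str)
            + ":"
            + s["treatment"].astype(str)
            + ":"
            + s["timepoint"].astype(str)
        )


def read_counts(counts_path, samplesheet_path) -> CountMatrix:
    """Read a genes x samples TSV and its sample sheet CSV.

    The TSV's first column holds gene IDs; remaining column names must
    match the ``sample`` column of the sheet exactly (as a set).
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samplesheet_path)
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in sheet.columns]
    if missing_cols:
        raise MetadataError(f"sample sheet missing columns: {missing_cols}")
    if sheet["sample"].duplicated().any():
        raise MetadataError("duplicate sample IDs in sample sheet")
    samples = sheet.set_index("sample")
    return CountMatrix(counts=counts, samples=samples)


def write_counts(cm: CountMatrix, counts_path, samplesheet_path) -> None:
    cm.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
    cm.samples.rename_axis("sample").reset_index().to_csv(samplesheet_path, index=False)


@dataclass
class GeneAnnotation:
    """Gene coordinates plus optional GO / TF-family / homolog maps.

    ``coords`` is indexed by gene ID with columns chrom, start, end, strand
    (1-based inclusive).  The maps may be partial: a gene absent from the GO
    map simply has no GO terms.
    """

    coords: pd.DataFrame
    go: dict[str, set[str]] = field(default_factory=dict)
    tf_family: dict[str, str] = field(default_factory=dict)
    homolog: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.coords.index.duplicated().any():
            dupes = self.coords.index[self.coords.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene IDs in annotation: {dupes[:5]}")
        bad = self.coords["start"] > self.coords["end"]
        if bad.any():
            raise FormatError(
                f"gene(s) with start > end: {self.coords.index[bad].tolist()[:5]}"
            )

    def go_terms(self, gene: str) -> set[str]:
        return self.go.get(gene, set())


def _parse_gff3_genes(gff3_path) -> pd.DataFrame:
    """Extract gene features from a GFF3 file via gffutils (in-memory DB).

    Lines are pre-validated so parse errors carry a line number.
    """
    import gffutils

    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{gff3_path}: malformed GFF3 line {lineno}: "
                    f"expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                int(fields[3]), int(fields[4])
            except ValueError:
                raise FormatError(
                    f"{gff3_path}: malformed GFF3 line {lineno}: "
                    "non-integer coordinates"
                ) from None

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="error",
    )
    rows = []
    for feat in db.features_of_type("gene"):
        rows.append((feat.id, feat.seqid, feat.start, feat.end, feat.strand or "."))
    if not rows:
        raise FormatError(f"{gff3_path}: no gene features found")
    df = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand"])
    if df["gene"].duplicated().any():
        dupes = df.loc[df["gene"].duplicated(), "gene"].unique().tolist()
        raise FormatError(f"duplicate gene ID(s) in GFF3: {dupes[:5]}")
    return df.set_index("gene")


def _read_two_col_map(path, multi: bool = False):
    """Two-column TSV gene -> value map.  ``multi`` collects sets per gene."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str).dropna()
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected >= 2 tab-separated columns")
    # tolerate a header row naming the columns
    first = str(df.iloc[0, 0]).lower()
    if first in {"gene", "gene_id", "geneid"}:
        df = df.iloc[1:]
    if multi:
        out: dict[str, set[str]] = {}
        for g, v in zip(df.iloc[:, 0], df.iloc[:, 1]):
            out.setdefault(g, set()).add(v)
        return out
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_annotation(
    gff3_path,
    go_map_path=None,
    tf_map_path=None,
    homolog_map_path=None,
) -> GeneAnnotation:
    """Assemble a :class:`GeneAnnotation` from a GFF3 plus optional maps."""
    coords = _parse_gff3_genes(gff3_path)
    go = _read_two_col_map(go_map_path, multi=True) if go_map_path else {}
    tf = _read_two_col_map(tf_map_path) if tf_map_path else {}
    hom = _read_two_col_map(homolog_map_path) if homolog_map_path else {}
    return GeneAnnotation(coords=coords, go=go, tf_family=tf, homolog=hom)


def read_edge_list(path) -> pd.DataFrame:
    """TF interaction edge list TSV: node_a, node_b, score (score optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    first = str(df.iloc[0, 0]).lower()
    if first in {"node_a", "source", "from"}:
        df = df.iloc[1:]
    if df.shape[1] == 2:
        df[2] = 1.0
    df = df.iloc[:, :3]
    df.columns = ["node_a", "node_b", "score"]
    df["score"] = df["score"].astype(float)
    return df.reset_index(drop=True)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write a machine-readable TSV; missing values as empty fields."""
    df.to_csv(path, sep="\t", index=index, na_rep="")


def to_tsv_string(df: pd.DataFrame, index: bool = True) -> str:
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=index, na_rep="")
    return buf.getvalue()
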
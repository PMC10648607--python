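"""Readers and assembly for transcript-abundance tables.

The on-disk dialect is the Salmon quantification table (``Name``, ``Length``,
``EffectiveLength``, ``TPM``, ``NumReads``; tab-separated), one file per
sample, plus a transcript-to-gene map and a sample-metadata table.  The
in-memory substrate for the whole pipeline is the
:class:`IsoformAbundanceMatrix`: transcripts x samples TPM values together
with the transcript-to-gene mapping.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from pathlib import Path

import pandas as pd

from .errors import FormatError

__all__ = [
    "IsoformAbundanceMatrix",
    "read_quant_table",
    "read_tx2gene",
    "read_metadata",
    "read_gene_list",
    "load_quant_dir",
    "assemble_matrix",
]

_VERSION_SUFFIX = r"\.\d+$"


def strip_version(ids: pd.Index | pd.Series) -> pd.Index | pd.Series:
    """Drop trailing '.N' version suffixes (Gencode dialect tolerance)."""
    return ids.str.replace(_VERSION_SUFFIX, "", regex=True)


@dataclasses.dataclass(frozen=True)
class IsoformAbundanceMatrix:
    """TPM values of transcript isoforms across samples.

    ``tpm`` is indexed by transcript ID with one column per sample;
    ``tx2gene`` is indexed by transcript ID with columns ``gene_id`` and
    ``biotype`` and covers every transcript in ``tpm``.
    """

    tpm: pd.DataFrame
    tx2gene: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.tpm.index.is_unique:
            raise FormatError("duplicate transcript IDs in abundance matrix")
        if not self.tpm.columns.is_unique:
            raise FormatError("duplicate sample IDs in abundance matrix")
        if (self.tpm.to_numpy() < 0).any():
            raise FormatError("negative TPM values in abundance matrix")
        missing = self.tpm.index.difference(self.tx2gene.index)
        if len(missing):
            raise FormatError(
                f"{len(missing)} transcripts lack a gene mapping "
                f"(e.g. {list(missing[:5])})"
            )

    @property
    def transcript_ids(self) -> pd.Index:
        return self.tpm.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.tpm.columns

    @property
    def gene_of(self) -> pd.Series:
        """Gene ID per transcript, aligned with the matrix rows."""
        return self.tx2gene["gene_id"].reindex(self.tpm.index)

    def subset_genes(self, gene_ids) -> "IsoformAbundanceMatrix":
        """Restrict to transcripts of the given genes (intersection with
        detected genes; unknown IDs are ignored)."""
        keep = self.gene_of.isin(pd.Index(gene_ids))
        idx = self.tpm.index[keep]
        return IsoformAbundanceMatrix(self.tpm.loc[idx], self.tx2gene.loc[idx])


def read_quant_table(path: str | Path, strip_versions: bool = True) -> pd.Series:
    """Read one per-sample quantification table into a TPM series indexed by
    transcript ID.

    Requires the ``Name`` and ``TPM`` columns; other columns are ignored.
    Raises :class:`FormatError` naming any missing column, or on duplicate
    transcript IDs (including collisions created by version stripping).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("Name", "TPM"):
        if col not in df.columns:
            raise FormatError(f"missing column '{col}' in {path}")
    ids = df["Name"].astype(str)
    if strip_versions:
        ids = strip_version(ids)
    tpm = pd.Series(df["TPM"].astype(float).to_numpy(), index=pd.Index(ids, name="transcript_id"))
    if not tpm.index.is_unique:
        dups = tpm.index[tpm.index.duplicated()].unique()
        raise FormatError(f"duplicate transcript IDs in {path}: {list(dups[:5])}")
    return tpm


def _read_table_sniff_header(path: Path, names: list[str]) -> pd.DataFrame:
    """Read a TSV that may or may not carry a header row; the header is
    assumed present when the first field starts with the first expected
    column name."""
    first = path.read_text().splitlines()[0] if path.stat().st_size else ""
    has_header = first.split("\t")[0].strip().lower().startswith(names[0].split("_")[0])
    if has_header:
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.strip().lower() for c in df.columns]
    else:
        df = pd.read_csv(path, sep="\t", header=None)
        df.columns = names[: df.shape[1]] + [
            f"extra_{i}" for i in range(df.shape[1] - len(names))
        ]
    return df


def read_tx2gene(path: str | Path, strip_versions: bool = True) -> pd.DataFrame:
    """Read a transcript-to-gene map (2 or 3 columns: transcript, gene,
    optional biotype; header optional).

    Returns a frame indexed by transcript ID with columns ``gene_id`` and
    ``biotype`` (defaulted to ``"unknown"`` when absent).  A transcript
    mapped to two different genes is a :class:`FormatError`; exact duplicate
    rows are collapsed.
    """
    path = Path(path)
    df = _read_table_sniff_header(path, ["transcript_id", "gene_id", "biotype"])
    if df.shape[1] < 2:
        raise FormatError(f"tx2gene file {path} needs >= 2 columns")
    df = df.rename(
        columns={df.columns[0]: "transcript_id", df.columns[1]: "gene_id"}
    )
    if "biotype" not in df.columns:
        if df.shape[1] >= 3:
            df = df.rename(columns={df.columns[2]: "biotype"})
        else:
            df["biotype"] = "unknown"
    df = df[["transcript_id", "gene_id", "biotype"]].astype(str)
    if strip_versions:
        df["transcript_id"] = strip_version(df["transcript_id"])
        df["gene_id"] = strip_version(df["gene_id"])
    df = df.drop_duplicates()
    if df["transcript_id"].duplicated().any():
        bad = df.loc[df["transcript_id"].duplicated(), "transcript_id"].unique()
        raise FormatError(
            f"transcripts mapped to multiple genes in {path}: {list(bad[:5])}"
        )
    return df.set_index("transcript_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample-metadata table (sample_id, type; header optional)."""
    path = Path(path)
    df = _read_table_sniff_header(path, ["sample_id", "type"])
    if df.shape[1] < 2:
        raise FormatError(f"metadata file {path} needs >= 2 columns")
    df = df.rename(columns={df.columns[0]: "sample_id", df.columns[1]: "type"})
    df = df[["sample_id", "type"]].astype(str)
    if df["sample_id"].duplicated().any():
        raise FormatError(f"duplicate sample IDs in {path}")
    return df.reset_index(drop=True)


def read_gene_list(path: str | Path, strip_versions: bool = True) -> list[str]:
    """Read a gene-ID list (one ID per line, blank lines ignored)."""
    ids = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if strip_versions:
        ids = list(strip_version(pd.Series(ids)))
    return ids


def load_quant_dir(
    quant_dir: str | Path, metadata: pd.DataFrame, strip_versions: bool = True
) -> dict[str, pd.Series]:
    """Locate and read one quant table per metadata sample.

    Accepts ``<sample>.quant.tsv``, ``<sample>.tsv``, ``<sample>.sf`` or the
    Salmon layout ``<sample>/quant.sf``.  Samples without a table raise a
    :class:`FormatError` listing them.
    """
    quant_dir = Path(quant_dir)
    columns: dict[str, pd.Series] = {}
    missing = []
    for sid in metadata["sample_id"]:
        for cand in (
            quant_dir / f"{sid}.quant.tsv",
            quant_dir / f"{sid}.tsv",
            quant_dir / f"{sid}.sf",
            quant_dir / sid / "quant.sf",
        ):
            if cand.is_file():
                columns[sid] = read_quant_table(cand, strip_versions=strip_versions)
                break
        else:
            missing.append(sid)
    if missing:
        raise FormatError(f"no quant table found for samples: {missing}")
    return columns


def assemble_matrix(
    columns: Mapping[str, pd.Series],
    tx2gene: pd.DataFrame,
    metadata: pd.DataFrame,
    protein_coding_only: bool = False,
    on_unmapped: str = "error",
) -> IsoformAbundanceMatrix:
    """Assemble per-sample TPM columns into an IsoformAbundanceMatrix.

    Rows are the union of transcripts over samples (sorted, so assembly is
    independent of input order); a transcript absent from a sample gets
    TPM 0, i.e. undetected isoforms are treated as absent.  With
    ``protein_coding_only`` transcripts of genes whose biotype is not
    ``protein_coding`` are dropped before analysis.  Transcripts missing
    from the map raise (``on_unmapped="error"``) or are dropped
    (``"drop"``).
    """
    if on_unmapped not in ("error", "drop"):
        raise ValueError(f"on_unmapped must be 'error' or 'drop', got {on_unmapped!r}")
    missing_samples = [s for s in metadata["sample_id"] if s not in columns]
    if missing_samples:
        raise FormatError(f"metadata samples without a quant column: {missing_samples}")

    union = pd.Index(sorted(set().union(*(columns[s].index for s in metadata["sample_id"]))),
                     name="transcript_id")
    tpm = pd.DataFrame(
        {sid: columns[sid].reindex(union).fillna(0.0) for sid in metadata["sample_id"]},
        index=union,
    )

    unmapped = union.difference(tx2gene.index)
    if len(unmapped):
        if on_unmapped == "error":
            raise FormatError(
                f"{len(unmapped)} transcripts absent from tx2gene "
                f"(e.g. {list(unmapped[:5])})"
            )
        tpm = tpm.drop(index=unmapped)
    mapping = tx2gene.reindex(tpm.index)

    if protein_coding_only:
        keep = mapping["biotype"] == "protein_coding"
        tpm, mapping = tpm.loc[keep], mapping.loc[keep]

    return IsoformAbundanceMatrix(tpm, mapping)
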
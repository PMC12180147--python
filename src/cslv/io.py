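"""Readers and writers for the tabular formats the toolkit touches.

Four kinds of tables move through the pipeline:

* a **marker manifest** mapping SNP-array markers to genomic coordinates
  (autosome 1-22, 1-based bp position),
* a **log R ratio (LRR) matrix**, samples x markers, in either a long
  Final-Report-like TSV (one row per sample/marker pair) or a wide TSV
  with one column per marker,
* a **phenotype table** (sample id, sex, group label, age in years,
  height in cm),
* the **CSLV feature table** of per-segment mean LRR values with columns
  labelled ``chr{c}_{q}`` (chromosome ``c``, segment index ``q``).

Only autosomes 1-22 are retained on ingestion; rows on X, Y, MT or any
other contig are dropped (and counted).  Missing LRR entries stay
missing — they are never silently turned into zeros, because an LRR of
0 means "nominal two copies", which is information, not absence.
"""

from __future__ import annotations

import logging
import re
from typing import IO, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tokens treated as "missing" when parsing LRR / phenotype fields
#: (compared case-insensitively after stripping whitespace)
MISSING_TOKENS = frozenset({"", "na", "nan"})

AUTOSOMES = tuple(range(1, 23))

#: default column names for long-format LRR files (Illumina Final-Report
#: style); a dialect mapping may override any of them
DEFAULT_LONG_DIALECT: Mapping[str, str] = {
    "sample": "Sample ID",
    "marker": "SNP Name",
    "chromosome": "Chr",
    "position": "Position",
    "lrr": "Log R Ratio",
    "baf": "B Allele Freq",
}

_REQUIRED_LONG_ROLES = ("sample", "marker", "chromosome", "position", "lrr")

SEGMENT_LABEL_RE = re.compile(r"^chr(\d+)_(\d+)$")

_CHROM_PREFIX_RE = re.compile(r"^chr", re.IGNORECASE)

MANIFEST_COLUMNS = ("marker_id", "chromosome", "position_bp")

PHENOTYPE_COLUMNS = ("sample_id", "sex", "group_label", "age", "height")


def normalize_chromosome(label: object) -> int | None:
    """Map a chromosome label to an autosome number, or ``None``.

    Accepts ``1``, ``"1"``, ``"chr1"``, ``"Chr1"`` and the like.  Labels
    that do not denote an autosome 1-22 (``"X"``, ``"Y"``, ``"MT"``,
    ``"chr23"``, ...) return ``None`` and are dropped by the readers.
    """
    if label is None:
        return None
    text = _CHROM_PREFIX_RE.sub("", str(label).strip())
    if not text.isdigit():
        return None
    value = int(text)
    return value if 1 <= value <= 22 else None


def _parse_numeric(series: pd.Series) -> pd.Series:
    """Parse a string column to float, mapping missing tokens to NaN.

    Goes through numpy's string parser, which is correctly rounded, so
    writing with 17 significant digits and reading back is bit-exact
    (pandas' own converter is not)."""
    cleaned = series.astype(str).str.strip()
    cleaned = cleaned.where(~cleaned.str.lower().isin(MISSING_TOKENS), "nan")
    values = cleaned.to_numpy(dtype=str).astype(np.float64)
    return pd.Series(values, index=series.index)


def canonical_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Validate a manifest and put it in canonical order.

    Canonical order is (chromosome, position_bp, marker_id); the
    marker_id tie-break makes the ordering deterministic when two
    markers share a position.
    """
    df = manifest.loc[:, list(MANIFEST_COLUMNS)].copy()
    df["marker_id"] = df["marker_id"].astype(str)
    df["chromosome"] = df["chromosome"].astype(int)
    df["position_bp"] = df["position_bp"].astype(int)
    if df["marker_id"].duplicated().any():
        dupes = df.loc[df["marker_id"].duplicated(), "marker_id"].tolist()
        raise ValueError(f"duplicate marker ids in manifest: {dupes[:5]}")
    bad = ~df["chromosome"].isin(AUTOSOMES)
    if bad.any():
        raise ValueError(
            f"manifest contains non-autosomal chromosome values: "
            f"{sorted(df.loc[bad, 'chromosome'].unique().tolist())}"
        )
    if (df["position_bp"] < 1).any():
        raise ValueError("manifest positions must be >= 1 (1-based)")
    df = df.sort_values(
        ["chromosome", "position_bp", "marker_id"], kind="stable"
    ).reset_index(drop=True)
    return df


def read_lrr_long(
    source: str | IO[str],
    dialect: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a long-format (Final-Report-like) LRR file.

    Parameters
    ----------
    source
        Path or text stream of a tab-delimited file with one row per
        (sample, marker) observation.
    dialect
        Optional mapping from the logical roles ``sample``, ``marker``,
        ``chromosome``, ``position``, ``lrr`` (and optionally ``baf``)
        to the column names actually present in the file.

    Returns
    -------
    (manifest, matrix)
        ``manifest`` is the canonical marker manifest; ``matrix`` is a
        samples x markers DataFrame (rows = sample ids in order of first
        appearance, columns = marker ids in manifest order, NaN =
        missing).  BAF and any extra columns are parsed and discarded;
        only the LRR signal is kept.
    """
    cols = dict(DEFAULT_LONG_DIALECT)
    if dialect:
        cols.update(dialect)
    raw = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    for role in _REQUIRED_LONG_ROLES:
        if cols[role] not in raw.columns:
            raise ValueError(
                f"required column for role '{role}' ({cols[role]!r}) not found; "
                f"available columns: {list(raw.columns)}"
            )

    chrom = raw[cols["chromosome"]].map(normalize_chromosome)
    n_dropped = int(chrom.isna().sum())
    if n_dropped:
        logger.info("dropped %d non-autosomal rows on read", n_dropped)
    keep = raw.loc[chrom.notna()].copy()
    keep["_chrom"] = chrom.loc[keep.index].astype(int)

    dup = keep.duplicated(subset=[cols["sample"], cols["marker"]])
    if dup.any():
        row = keep.loc[dup.idxmax()]
        raise ValueError(
            "duplicate (sample, marker) pair: "
            f"({row[cols['sample']]!r}, {row[cols['marker']]!r})"
        )

    marker_coords = keep[[cols["marker"], "_chrom", cols["position"]]].drop_duplicates()
    if marker_coords[cols["marker"]].duplicated().any():
        bad = marker_coords.loc[
            marker_coords[cols["marker"]].duplicated(), cols["marker"]
        ].iloc[0]
        raise ValueError(f"marker {bad!r} has conflicting coordinates")
    manifest = canonical_manifest(
        marker_coords.rename(
            columns={
                cols["marker"]: "marker_id",
                "_chrom": "chromosome",
                cols["position"]: "position_bp",
            }
        )
    )

    keep["_lrr"] = _parse_numeric(keep[cols["lrr"]])
    sample_order = keep[cols["sample"]].drop_duplicates().tolist()
    matrix = keep.pivot(index=cols["sample"], columns=cols["marker"], values="_lrr")
    matrix = matrix.reindex(index=sample_order, columns=manifest["marker_id"])
    matrix.index.name = "sample_id"
    matrix.columns.name = "marker_id"
    return manifest, matrix


def read_manifest(source: str | IO[str]) -> pd.DataFrame:
    """Read a manifest TSV with columns [marker_id, chr, position]."""
    raw = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    names = {c.lower(): c for c in raw.columns}
    def pick(*options: str) -> str:
        for o in options:
            if o in names:
                return names[o]
        raise ValueError(
            f"manifest needs one of columns {options}; found {list(raw.columns)}"
        )
    marker_col = pick("marker_id", "snp name", "marker")
    chr_col = pick("chr", "chromosome")
    pos_col = pick("position", "position_bp", "pos")
    chrom = raw[chr_col].map(normalize_chromosome)
    n_dropped = int(chrom.isna().sum())
    if n_dropped:
        logger.info("dropped %d non-autosomal manifest rows", n_dropped)
    keep = raw.loc[chrom.notna()]
    return canonical_manifest(
        pd.DataFrame(
            {
                "marker_id": keep[marker_col],
                "chromosome": chrom.loc[keep.index].astype(int),
                "position_bp": keep[pos_col].astype(int),
            }
        )
    )


def read_lrr_wide(
    source: str | IO[str], manifest_source: str | IO[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a wide LRR TSV (samples x markers) plus its manifest TSV.

    The first column of the wide file holds sample ids; every remaining
    column must be a marker present in the manifest, and vice versa.
    Produces the same (manifest, matrix) pair as :func:`read_lrr_long`
    on equivalent content.
    """
    manifest = read_manifest(manifest_source)
    raw = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    sample_col = raw.columns[0]
    marker_cols = list(raw.columns[1:])
    known = set(manifest["marker_id"])
    unknown = [m for m in marker_cols if m not in known]
    if unknown:
        raise ValueError(f"marker column {unknown[0]!r} absent from manifest")
    if len(marker_cols) != len(known):
        missing = sorted(known - set(marker_cols))
        raise ValueError(
            f"dimension mismatch: manifest has {len(known)} markers but the "
            f"wide file has {len(marker_cols)} columns (e.g. missing {missing[:3]})"
        )
    if raw[sample_col].duplicated().any():
        bad = raw.loc[raw[sample_col].duplicated(), sample_col].iloc[0]
        raise ValueError(f"duplicate sample id {bad!r} in wide file")
    matrix = pd.DataFrame(
        {m: _parse_numeric(raw[m]).to_numpy() for m in marker_cols},
        index=raw[sample_col].tolist(),
    )
    matrix = matrix.reindex(columns=manifest["marker_id"])
    matrix.index.name = "sample_id"
    matrix.columns.name = "marker_id"
    return manifest, matrix


def write_manifest(manifest: pd.DataFrame, sink: str | IO[str]) -> None:
    out = canonical_manifest(manifest).rename(
        columns={"chromosome": "chr", "position_bp": "position"}
    )
    out.to_csv(sink, sep="\t", index=False)


def write_lrr_wide(matrix: pd.DataFrame, sink: str | IO[str]) -> None:
    """Write a samples x markers matrix as a wide TSV (full precision)."""
    out = matrix.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(sink, sep="\t", index=False, float_format="%.17g")


def write_lrr_long(
    matrix: pd.DataFrame,
    manifest: pd.DataFrame,
    sink: str | IO[str],
    baf: float | None = None,
) -> None:
    """Write a long-format LRR TSV in Final-Report column layout.

    Missing entries are written as empty fields.  If ``baf`` is given, a
    constant "B Allele Freq" column is emitted (a placeholder; BAF is
    never used downstream).
    """
    manifest = canonical_manifest(manifest)
    n_s, n_m = matrix.shape
    long = pd.DataFrame(
        {
            "Sample ID": np.repeat(np.asarray(matrix.index, dtype=object), n_m),
            "SNP Name": np.tile(manifest["marker_id"].to_numpy(), n_s),
            "Chr": np.tile(manifest["chromosome"].to_numpy(), n_s),
            "Position": np.tile(manifest["position_bp"].to_numpy(), n_s),
            "Log R Ratio": matrix.to_numpy().ravel(),
        }
    )
    if baf is not None:
        long["B Allele Freq"] = baf
    long.to_csv(sink, sep="\t", index=False, float_format="%.17g", na_rep="")


def parse_segment_label(label: str) -> tuple[int, int]:
    """Split ``"chr6_2"`` into ``(6, 2)``; raise on anything else."""
    m = SEGMENT_LABEL_RE.match(label)
    if not m:
        raise ValueError(f"malformed segment label: {label!r}")
    return int(m.group(1)), int(m.group(2))


def sorted_segment_labels(labels) -> list[str]:
    """Order segment labels by (chromosome, segment index)."""
    return sorted(labels, key=parse_segment_label)


def write_feature_table(table: pd.DataFrame, sink: str | IO[str]) -> None:
    """Write a CSLV feature table as CSV.

    First column is ``sample_id``; segment columns follow in
    (chromosome, segment-index) order.  Values are written with 17
    significant digits so ``read(write(t))`` reproduces ``t`` exactly.
    """
    cols = sorted_segment_labels(table.columns)
    out = table.loc[:, cols].copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(sink, index=False, float_format="%.17g")


def read_feature_table(source: str | IO[str]) -> pd.DataFrame:
    raw = pd.read_csv(source, dtype={"sample_id": str}, float_precision="round_trip")
    if "sample_id" not in raw.columns:
        raise ValueError("feature table must have a 'sample_id' first column")
    for col in raw.columns[1:]:
        parse_segment_label(col)  # raises naming the offending column
    table = raw.set_index("sample_id")
    table.index.name = "sample_id"
    return table.astype(float)


def read_phenotypes(source: str | IO[str]) -> pd.DataFrame:
    """Read a phenotype CSV [sample_id, sex, group_label, age, height].

    sex / group_label stay strings with NaN for missing; age and height
    are floats.  Heights, when present, must be finite and positive.
    """
    raw = pd.read_csv(source, dtype={"sample_id": str}, keep_default_na=False)
    missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"phenotype table missing columns: {missing_cols}")
    if raw["sample_id"].duplicated().any():
        bad = raw.loc[raw["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id {bad!r} in phenotype table")
    df = raw.loc[:, list(PHENOTYPE_COLUMNS)].copy()
    for col in ("sex", "group_label"):
        stripped = df[col].astype(str).str.strip()
        df[col] = stripped.mask(stripped.str.lower().isin(MISSING_TOKENS))
    for col in ("age", "height"):
        df[col] = _parse_numeric(df[col])
    heights = df["height"].dropna()
    if ((heights <= 0) | ~np.isfinite(heights)).any():
        raise ValueError("heights must be finite and positive when present")
    if (df["age"].dropna() < 0).any():
        raise ValueError("ages must be non-negative")
    return df


def write_phenotypes(phenotypes: pd.DataFrame, sink: str | IO[str]) -> None:
    phenotypes.loc[:, list(PHENOTYPE_COLUMNS)].to_csv(
        sink, index=False, float_format="%.17g", na_rep=""
    )
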
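"""Fixed partitioning of autosomes into segments and the CSLV feature table.

CSLV (chromosome-scale length variation) is the mean log R ratio of a
sample over a fixed segment of a chromosome: 0 is the nominal two-copy
state, positive values indicate net duplication and negative values net
deletion across the segment.  With the default four segments per
chromosome over the 22 autosomes this yields the 88-number genome
representation used throughout the toolkit.

This is deliberately *not* CNV calling: no change-point detection, no
HMM, no GC-wave correction — just means over a fixed partition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import canonical_manifest

logger = logging.getLogger(__name__)

MODES = ("equal_marker_count", "equal_bp_span")


@dataclass(frozen=True)
class Segment:
    """One chromosome segment.

    ``start``/``stop`` index the canonically sorted manifest (half-open,
    global row positions); ``bp_start``/``bp_stop`` give the half-open bp
    interval the segment spans (informational).
    """

    chromosome: int
    q: int
    start: int
    stop: int
    bp_start: int
    bp_stop: int

    @property
    def label(self) -> str:
        return f"chr{self.chromosome}_{self.q}"

    @property
    def n_markers(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class SegmentScheme:
    """An ordered partition of every autosome in a manifest into segments."""

    segments: tuple[Segment, ...]
    k: int
    mode: str
    #: (chromosome, marker count) pairs — a fingerprint used to verify a
    #: matrix/manifest was built from the same marker set
    chromosome_sizes: tuple[tuple[int, int], ...] = field(repr=False)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.segments]

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def marker_counts(self) -> np.ndarray:
        return np.array([s.n_markers for s in self.segments])

    def describe(self) -> list[dict]:
        """JSON-ready description (one dict per segment)."""
        return [
            {
                "label": s.label,
                "chromosome": s.chromosome,
                "q": s.q,
                "n_markers": s.n_markers,
                "bp_start": s.bp_start,
                "bp_end": s.bp_stop,
            }
            for s in self.segments
        ]


def _balanced_sizes(m: int, k: int) -> list[int]:
    # maximal-balanced split, larger segments first
    base, rem = divmod(m, k)
    return [base + 1] * rem + [base] * (k - rem)


def make_segments(
    manifest: pd.DataFrame, k: int = 4, mode: str = "equal_marker_count"
) -> SegmentScheme:
    """Partition each autosome of ``manifest`` into ``k`` segments.

    ``equal_marker_count`` (default) splits each chromosome's
    position-sorted markers into k runs whose sizes differ by at most
    one, larger runs first; every chromosome must carry at least k
    markers.  ``equal_bp_span`` cuts the chromosome's bp extent
    [min_pos, max_pos + 1) into k equal intervals and assigns markers by
    position; intervals may end up empty (warned).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    manifest = canonical_manifest(manifest)
    segments: list[Segment] = []
    sizes: list[tuple[int, int]] = []
    for chrom, block in manifest.groupby("chromosome", sort=True):
        m = len(block)
        offset = int(block.index[0])
        positions = block["position_bp"].to_numpy()
        sizes.append((int(chrom), m))
        if mode == "equal_marker_count":
            if m < k:
                raise ValueError(
                    f"chromosome {chrom} has {m} markers, fewer than k={k}"
                )
            start = 0
            for q, size in enumerate(_balanced_sizes(m, k), start=1):
                stop = start + size
                segments.append(
                    Segment(
                        chromosome=int(chrom),
                        q=q,
                        start=offset + start,
                        stop=offset + stop,
                        bp_start=int(positions[start]),
                        bp_stop=int(positions[stop - 1]) + 1,
                    )
                )
                start = stop
        else:  # equal_bp_span
            lo, hi = int(positions[0]), int(positions[-1]) + 1
            edges = np.linspace(lo, hi, k + 1)
            # markers with position in [edges[q-1], edges[q])
            cuts = np.searchsorted(positions, edges[1:-1], side="left")
            bounds = [0, *cuts.tolist(), m]
            for q in range(1, k + 1):
                start, stop = bounds[q - 1], bounds[q]
                if start == stop:
                    warnings.warn(
                        f"segment chr{chrom}_{q} is empty under equal_bp_span",
                        stacklevel=2,
                    )
                segments.append(
                    Segment(
                        chromosome=int(chrom),
                        q=q,
                        start=offset + start,
                        stop=offset + stop,
                        bp_start=int(np.floor(edges[q - 1])),
                        bp_stop=int(np.floor(edges[q])),
                    )
                )
    return SegmentScheme(
        segments=tuple(segments), k=k, mode=mode, chromosome_sizes=tuple(sizes)
    )


def _check_alignment(
    matrix: pd.DataFrame, manifest: pd.DataFrame, scheme: SegmentScheme
) -> pd.DataFrame:
    manifest = canonical_manifest(manifest)
    sizes = tuple(
        (int(c), len(b)) for c, b in manifest.groupby("chromosome", sort=True)
    )
    if sizes != scheme.chromosome_sizes:
        raise ValueError("segment scheme was not built from this manifest")
    if set(matrix.columns) != set(manifest["marker_id"]):
        raise ValueError("matrix columns do not match manifest markers")
    return matrix.reindex(columns=manifest["marker_id"])


def compute_cslv(
    matrix: pd.DataFrame,
    manifest: pd.DataFrame,
    scheme: SegmentScheme,
    min_observed_fraction: float = 0.9,
) -> pd.DataFrame:
    """Mean LRR per segment per sample — the CSLV feature table.

    An entry is the arithmetic mean of the sample's *observed* (non-
    missing) LRR values over the segment's markers, provided the
    observed fraction reaches ``min_observed_fraction``; otherwise the
    entry is missing.  No imputation is ever performed.
    """
    if not 0 < min_observed_fraction <= 1:
        raise ValueError("min_observed_fraction must be in (0, 1]")
    aligned = _check_alignment(matrix, manifest, scheme)
    values = aligned.to_numpy(dtype=float)
    out = np.full((values.shape[0], scheme.n_segments), np.nan)
    for j, seg in enumerate(scheme.segments):
        block = values[:, seg.start : seg.stop]
        if block.shape[1] == 0:
            continue  # empty segment stays missing
        observed = ~np.isnan(block)
        n_obs = observed.sum(axis=1)
        with np.errstate(invalid="ignore"):
            means = np.nansum(block, axis=1) / n_obs
        frac = n_obs / block.shape[1]
        means[frac < min_observed_fraction] = np.nan
        out[:, j] = means
    table = pd.DataFrame(out, index=matrix.index, columns=scheme.labels)
    table.index.name = "sample_id"
    return table


def filter_complete(table: pd.DataFrame) -> pd.DataFrame:
    """Keep only samples with a value in every segment column.

    The complete-case rule: samples with any missing segment value are
    excluded rather than imputed.  The column set is unchanged; an empty
    result is allowed.
    """
    kept = table.dropna(axis=0, how="any")
    n_dropped = len(table) - len(kept)
    if n_dropped:
        logger.info(
            "complete-case filter dropped %d of %d samples", n_dropped, len(table)
        )
    return kept


def summarize_segment_distribution(
    table: pd.DataFrame,
    segment_label: str,
    n_bins: int = 50,
    value_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of one segment's CSLV values across samples.

    Returns ``(bin_edges, counts)`` with equally spaced edges; counts
    sum to the number of non-missing entries in the column.
    """
    if segment_label not in table.columns:
        raise ValueError(f"unknown segment label: {segment_label!r}")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    values = table[segment_label].dropna().to_numpy()
    counts, edges = np.histogram(values, bins=n_bins, range=value_range)
    return edges, counts
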
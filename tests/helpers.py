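"""Shared test utilities: independent oracles and tiny builders."""

from __future__ import annotations

import numpy as np
import pandas as pd


def mann_whitney_auc(scores, labels) -> float:
    """Exhaustive pair-counting AUC: P(pos > neg) + 0.5 P(tie).

    Deliberately brute-force and independent of the ROC-curve code path
    it is used to check.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def tiny_manifest(per_chrom: dict[int, int], spacing: int = 100) -> pd.DataFrame:
    """Manifest with ``per_chrom[c]`` evenly spaced markers on each
    chromosome c."""
    rows = []
    for c, m in sorted(per_chrom.items()):
        for i in range(m):
            rows.append((f"t{c:02d}_{i:03d}", c, 1 + i * spacing))
    return pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp"])


def long_tsv(rows, header=("Sample ID", "SNP Name", "Chr", "Position", "Log R Ratio")) -> str:
    """Build a long-format LRR TSV string from row tuples."""
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(str(x) for x in row))
    return "\n".join(lines) + "\n"
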
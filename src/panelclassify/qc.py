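"""Per-sample panel sequencing QC metrics and pass/fail rules.

The somatic arm requires >= 300x coverage in at least 80% of target
regions; the germline arm requires >= 200x in at least 80%. Uniformity is
the fraction of target bases covered at or above 0.2x the mean target
depth (the factor is configurable). Read-level metrics (raw reads,
filtered fraction, duplication rate, on-target reads) are ingested from
upstream tool summaries rather than recomputed from alignments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_COVERAGE_THRESHOLDS",
    "QCSummary",
    "region_coverage_fractions",
    "uniformity",
    "sample_pass",
    "summarize_sample",
    "qc_report",
    "read_region_depths",
    "read_per_base_depths",
]

DEFAULT_COVERAGE_THRESHOLDS: tuple[int, ...] = (100, 200, 300, 400, 500)

#: (coverage threshold, minimum fraction of regions) per calling mode.
PASS_RULES: Mapping[str, tuple[int, float]] = {
    "somatic": (300, 0.80),
    "germline": (200, 0.80),
}


@dataclass(frozen=True)
class QCSummary:
    sample_id: str
    mean_target_depth: float
    uniformity: float
    region_cov_fracs: Mapping[int, float]
    raw_reads: Optional[int] = None
    pct_filtered: Optional[float] = None
    dup_rate: Optional[float] = None
    on_target_reads: Optional[int] = None

    def __post_init__(self) -> None:
        fractions = [self.uniformity, *self.region_cov_fracs.values()]
        if any(not 0.0 <= f <= 1.0 for f in fractions):
            raise ValueError("QC fractions must lie in [0, 1]")
        ordered = [self.region_cov_fracs[t] for t in sorted(self.region_cov_fracs)]
        if any(a < b - 1e-12 for a, b in zip(ordered, ordered[1:])):
            raise ValueError("region coverage fractions must be non-increasing in threshold")

    @property
    def pass_somatic(self) -> bool:
        return sample_pass(self, "somatic")

    @property
    def pass_germline(self) -> bool:
        return sample_pass(self, "germline")


def region_coverage_fractions(
    depths: Sequence[float], thresholds: Sequence[int] = DEFAULT_COVERAGE_THRESHOLDS
) -> dict[int, float]:
    """Fraction of target regions with mean depth >= t, for each threshold."""
    if len(depths) == 0:
        raise ValueError("empty region depth list")
    arr = np.asarray(depths, dtype=float)
    return {int(t): float(np.mean(arr >= t)) for t in thresholds}


def uniformity(per_base_depths: Sequence[float], factor: float = 0.2) -> float:
    """Fraction of target bases with depth >= factor * mean target depth.

    Scale-invariant: multiplying every depth by a positive constant leaves
    the value unchanged. Defined as 0 for an all-zero profile.
    """
    arr = np.asarray(per_base_depths, dtype=float)
    if arr.size == 0:
        raise ValueError("empty per-base depth vector")
    mean = arr.mean()
    if mean == 0:
        return 0.0
    return float(np.mean(arr >= factor * mean))


def sample_pass(qc: QCSummary, mode: str) -> bool:
    """Apply the per-mode coverage pass rule (boundary inclusive)."""
    try:
        threshold, min_fraction = PASS_RULES[mode]
    except KeyError:
        raise ValueError(f"unknown mode {mode!r}; expected one of {sorted(PASS_RULES)}")
    if threshold not in qc.region_cov_fracs:
        raise ValueError(f"coverage fraction at {threshold}x missing from QC summary")
    return qc.region_cov_fracs[threshold] >= min_fraction


def summarize_sample(
    sample_id: str,
    region_depths: Sequence[float],
    per_base_depths: Sequence[float] | None = None,
    thresholds: Sequence[int] = DEFAULT_COVERAGE_THRESHOLDS,
    uniformity_factor: float = 0.2,
    **read_metrics,
) -> QCSummary:
    """Build a :class:`QCSummary` from depth vectors.

    When per-base depths are unavailable, uniformity is computed on the
    per-region mean depths (a coarser but common approximation).
    """
    base = per_base_depths if per_base_depths is not None else region_depths
    return QCSummary(
        sample_id=sample_id,
        mean_target_depth=float(np.mean(np.asarray(region_depths, dtype=float))),
        uniformity=uniformity(base, uniformity_factor),
        region_cov_fracs=region_coverage_fractions(region_depths, thresholds),
        **read_metrics,
    )


def qc_report(summaries: Sequence[QCSummary], path: str | Path) -> pd.DataFrame:
    """Write the per-sample QC table (TSV) plus a JSON twin.

    Returns the table as a DataFrame; the JSON twin at ``<path>.json``
    re-parses to the same values.
    """
    if not summaries:
        raise ValueError("no QC summaries to report")
    path = Path(path)
    rows = []
    for s in summaries:
        row = {
            "sample_id": s.sample_id,
            "raw_reads": s.raw_reads,
            "pct_filtered": s.pct_filtered,
            "dup_rate": s.dup_rate,
            "on_target_reads": s.on_target_reads,
            "mean_target_depth": s.mean_target_depth,
            "uniformity": s.uniformity,
        }
        for t in sorted(s.region_cov_fracs):
            row[f"frac_regions_{t}x"] = s.region_cov_fracs[t]
        row["pass_somatic"] = s.pass_somatic
        row["pass_germline"] = s.pass_germline
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(rows, indent=2, default=float) + "\n"
    )
    return df


def read_region_depths(path: str | Path) -> pd.DataFrame:
    """Read a 4-column region depth table: chrom, start, end, mean_depth."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start", "end", "mean_depth"],
        header=None,
        comment="#",
    )
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: region with start >= end")
    return df


def read_per_base_depths(path: str | Path) -> pd.DataFrame:
    """Read a 3-column per-base depth table: chrom, pos (1-based), depth."""
    return pd.read_csv(
        path, sep="\t", names=["chrom", "pos", "depth"], header=None, comment="#"
    )
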
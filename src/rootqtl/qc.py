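"""Marker-cleaning rules for the SNP panel.

Removal proceeds in a fixed order so the report reconciles exactly:
monomorphic markers first, then call rate below the threshold, then
minor allele frequency at or below the threshold. MAF is computed on
non-missing calls with heterozygotes contributing one allele copy each;
the MAF cut is strict (> maf_min retained) and the call-rate cut is
inclusive (>= call_rate_min retained).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from .panel import GenotypePanel

log = logging.getLogger(__name__)


@dataclass
class QCReport:
    n_input_markers: int
    n_removed_monomorphic: int
    n_removed_callrate: int
    n_removed_maf: int
    n_retained: int
    maf_min: float
    call_rate_min: float

    def __post_init__(self):
        removed = (
            self.n_removed_monomorphic + self.n_removed_callrate + self.n_removed_maf
        )
        assert self.n_input_markers == removed + self.n_retained

    def to_json(self, **kw) -> str:
        return json.dumps(asdict(self), **kw)


def minor_allele_freq(panel: GenotypePanel) -> np.ndarray:
    """Per-marker MAF over non-missing calls (hets = one copy each)."""
    f = panel.allele_freq()
    return np.minimum(f, 1.0 - f)


def filter_markers(
    panel: GenotypePanel,
    maf_min: float = 0.05,
    call_rate_min: float = 0.95,
) -> tuple:
    """Apply the marker-cleaning rules; genotype rows are untouched.

    Returns ``(filtered_panel, QCReport)``. Removing every marker is a
    warning, not an error.
    """
    if panel.n_markers == 0:
        report = QCReport(0, 0, 0, 0, 0, maf_min, call_rate_min)
        return panel, report

    n_states = np.array(
        [len(np.unique(col[~np.isnan(col)])) for col in panel.dosage.T]
    )
    mono = n_states < 2
    call = panel.call_rate()
    low_call = (call < call_rate_min) & ~mono
    maf = minor_allele_freq(panel)
    low_maf = ~(maf > maf_min) & ~mono & ~low_call

    keep = ~(mono | low_call | low_maf)
    report = QCReport(
        n_input_markers=panel.n_markers,
        n_removed_monomorphic=int(mono.sum()),
        n_removed_callrate=int(low_call.sum()),
        n_removed_maf=int(low_maf.sum()),
        n_retained=int(keep.sum()),
        maf_min=maf_min,
        call_rate_min=call_rate_min,
    )
    if report.n_retained == 0:
        log.warning("QC removed every marker; returning an empty panel")
    markers = [m for m, k in zip(panel.marker_ids, keep) if k]
    return panel.subset_markers(markers), report
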
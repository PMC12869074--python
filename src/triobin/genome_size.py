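"""Genome-size estimation from k-mer multiplicity spectra.

The estimator is the transparent peak/cutoff form of the classical
spectrum method: with a coverage peak at depth ``c``, genome size is
total k-mer abundance divided by ``c``; the *error-excluded* variant
drops abundance below the first valley of the spectrum, where k-mers
produced by sequencing errors concentrate.

Two modes mirror spectrum-fitting practice:

* **homozygous** — ``c`` is the spectrum's main peak (argmax above the
  error valley), or a supplied expected coverage when no peak is
  detectable;
* **heterozygous** — ``c`` is the *expected homozygous coverage* given
  by the caller, and the spectrum must show a second mode in the
  half-depth band [0.25c, 0.75c] where haplotype-specific k-mers of a
  diploid sample sit.  A binned (single-haplotype) read set has no such
  mode, and the estimate is flagged failed — the expected behaviour for
  haplotype-partitioned reads, not an error of the method.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SpectrumSignalError
from .kmer_core import KmerHistogram

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"

#: histogram tail above this multiplicity is pooled before estimation
DEFAULT_MAX_MULTIPLICITY = 10_000


def find_error_cutoff(hist: KmerHistogram) -> int:
    """First local minimum of the spectrum scanning up from multiplicity 1.

    Error k-mers dominate low multiplicities, so the first valley
    separates them from genomic signal.  A monotone non-increasing
    spectrum has no valley and no signal peak: that is a flagged
    failure (:class:`SpectrumSignalError`), mirroring read sets whose
    spectrum cannot support an estimate.
    """
    dense = hist.dense
    if hist.total_distinct == 0:
        raise SpectrumSignalError("empty histogram")
    for m in range(1, dense.size - 1):
        if dense[m] < dense[m + 1]:
            return m
    raise SpectrumSignalError("monotone non-increasing spectrum: no signal peak")


@dataclass
class SizeEstimate:
    mode: str
    raw_size: float | None
    error_excluded_size: float | None
    error_cutoff: int
    peak_depth: float | None
    expected_hom_cov: float | None = None
    #: heterozygous mode: abundance fraction in the half-depth band
    het_band_fraction: float | None = None
    failed: bool = False
    note: str = ""
    label: str = ""


def _band_has_mode(dense: np.ndarray, c: float, cutoff: int) -> bool:
    """Is there a half-depth mode in the band [0.25c, 0.75c]?

    A diploid spectrum carries haplotype-specific k-mers at depth c/2,
    so inside the band the curve rises to that mode and then turns
    downward before the homozygous flank takes over.  The detector
    looks for a *statistically significant descent* between band
    positions (difference > 3 sd under Poisson counting noise).  A
    single-haplotype spectrum rises monotonically through the band —
    its noise-level dips stay within the guard — so it fails the test,
    which is the expected outcome for binned read sets.
    """
    lo = max(int(np.ceil(0.25 * c)), cutoff + 1)
    hi = min(int(np.floor(0.75 * c)), dense.size - 1)
    for i in range(lo, hi):
        for j in (1, 2):
            if i + j > hi:
                break
            a, b = float(dense[i]), float(dense[i + j])
            if a - b > 3.0 * np.sqrt(a + b + 1.0):
                return True
    return False


def estimate_size(
    hist: KmerHistogram,
    mode: str = HOMOZYGOUS,
    expected_hom_cov: float | None = None,
    max_multiplicity: int = DEFAULT_MAX_MULTIPLICITY,
    label: str = "",
) -> SizeEstimate:
    """Estimate genome size from a k-mer spectrum.

    Returns raw and error-excluded sizes in bases.  Failure modes are
    reported on the returned object (``failed``/``note``) rather than
    raised, except for invalid configuration (heterozygous mode without
    ``expected_hom_cov``).
    """
    if mode not in (HOMOZYGOUS, HETEROZYGOUS):
        raise ConfigurationError(f"unknown mode {mode!r}")
    if mode == HETEROZYGOUS and expected_hom_cov is None:
        raise ConfigurationError("heterozygous mode requires expected_hom_cov")

    hist = hist.pool_tail(max_multiplicity)
    dense = hist.dense
    m = np.arange(dense.size, dtype=np.float64)
    total_abundance = float((m * dense).sum())

    try:
        cutoff = find_error_cutoff(hist)
        no_valley = False
    except SpectrumSignalError:
        cutoff = 1
        no_valley = True

    if mode == HOMOZYGOUS:
        if not no_valley:
            peak_m = int(np.argmax(dense[cutoff + 1 :]) + cutoff + 1)
            # centroid over the full-width-at-half-maximum region
            # de-discretises the peak depth and is stable when two bins
            # near the mode are a statistical tie
            half = dense[peak_m] / 2.0
            lo = peak_m
            while lo - 1 > cutoff and dense[lo - 1] >= half:
                lo -= 1
            hi = peak_m
            while hi + 1 < dense.size and dense[hi + 1] >= half:
                hi += 1
            weights = dense[lo : hi + 1].astype(np.float64)
            c = float((m[lo : hi + 1] * weights).sum() / weights.sum())
        elif expected_hom_cov is not None:
            c = float(expected_hom_cov)
        else:
            return SizeEstimate(
                mode, None, None, cutoff, None, expected_hom_cov,
                failed=True, note="no detectable spectrum peak", label=label,
            )
    else:
        c = float(expected_hom_cov)

    raw = total_abundance / c
    excluded = float((m[cutoff:] * dense[cutoff:]).sum()) / c
    est = SizeEstimate(
        mode, raw, excluded, cutoff, c, expected_hom_cov, label=label
    )
    if mode == HETEROZYGOUS:
        lo = max(int(np.floor(0.25 * c)), 1)
        hi = min(int(np.ceil(0.75 * c)), dense.size - 1)
        band = float((m[lo : hi + 1] * dense[lo : hi + 1]).sum())
        est.het_band_fraction = band / total_abundance if total_abundance else 0.0
        if not _band_has_mode(dense, c, cutoff):
            est.failed = True
            est.note = "no half-depth heterozygous peak (single-haplotype spectrum?)"
    return est


def size_report(estimates) -> pd.DataFrame:
    """Mb-scaled report table, one row per estimate; failures render 'fail'."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "readset": e.label,
                "mode": e.mode,
                "size_mb": "fail" if e.failed else round(e.raw_size / 1e6, 3),
                "error_excluded_mb": "fail" if e.failed else round(e.error_excluded_size / 1e6, 3),
                "error_cutoff": e.error_cutoff,
                "peak_depth": e.peak_depth,
                "note": e.note,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["readset", "mode", "size_mb", "error_excluded_mb", "error_cutoff", "peak_depth", "note"],
    )
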
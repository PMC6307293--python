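"""Copy-number quantification from qPCR and droplet-digital PCR.

qPCR uses comparative-Ct (2^-DeltaDeltaCt) relative quantification against a
two-copy reference locus and a two-copy calibrator sample, so the relative
quantity RQ maps to diploid copies as 2 * RQ. ddPCR uses single-dye Poisson
occupancy: with a fraction f of negative droplets per channel, the mean
target molecules per droplet is lambda = -ln(f), and the copy number is
2 * lambda_target / lambda_reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import CopyNumberEstimate

__all__ = [
    "QpcrMeasurement",
    "DdpcrWell",
    "rq_from_ddct",
    "ddpcr_copy_number",
    "genotype_from_copies",
    "estimate_qpcr",
    "estimate_ddpcr",
]


@dataclass
class QpcrMeasurement:
    """Replicate Ct values for target and reference channels of one sample."""

    sample_id: str
    ct_target: np.ndarray  # cycles, >= 1 replicate
    ct_reference: np.ndarray
    calibrator_delta_ct: float | None = None  # DeltaCt of the 2-copy calibrator

    def __post_init__(self) -> None:
        self.ct_target = np.atleast_1d(np.asarray(self.ct_target, dtype=float))
        self.ct_reference = np.atleast_1d(np.asarray(self.ct_reference, dtype=float))
        if self.ct_target.size < 1 or self.ct_reference.size < 1:
            raise ValueError("need >= 1 Ct replicate per channel")
        if not (np.isfinite(self.ct_target).all()
                and np.isfinite(self.ct_reference).all()):
            raise ValueError("non-finite Ct value")


@dataclass
class DdpcrWell:
    """Positive/negative droplet counts for target and reference dyes."""

    positives_target: int
    negatives_target: int
    positives_reference: int
    negatives_reference: int

    def __post_init__(self) -> None:
        counts = (self.positives_target, self.negatives_target,
                  self.positives_reference, self.negatives_reference)
        if any(c < 0 for c in counts):
            raise ValueError("droplet counts must be >= 0")
        if self.positives_target + self.negatives_target == 0:
            raise ValueError("no droplets in target channel")
        if self.positives_reference + self.negatives_reference == 0:
            raise ValueError("no droplets in reference channel")


def rq_from_ddct(measurement: QpcrMeasurement) -> tuple[float, float]:
    """Comparative-Ct relative quantity and implied diploid copy number.

    DeltaCt = mean(Ct_target) - mean(Ct_reference); DeltaDeltaCt subtracts
    the calibrator's DeltaCt; RQ = 2^-DeltaDeltaCt. The calibrator carries
    two copies, so copies = 2 * RQ.
    """
    if measurement.calibrator_delta_ct is None:
        raise ValueError("calibrator DeltaCt required for 2^-DDCt quantification")
    dct = float(measurement.ct_target.mean() - measurement.ct_reference.mean())
    ddct = dct - measurement.calibrator_delta_ct
    rq = 2.0 ** (-ddct)
    return rq, 2.0 * rq


def ddpcr_copy_number(well: DdpcrWell) -> float:
    """Copy number from Poisson droplet occupancy of the two channels."""
    tot_t = well.positives_target + well.negatives_target
    tot_r = well.positives_reference + well.negatives_reference
    if well.negatives_target == 0 or well.negatives_reference == 0:
        raise ValueError(
            "all droplets positive (saturated well): dilute the sample and rerun"
        )
    lam_t = -np.log(well.negatives_target / tot_t)
    lam_r = -np.log(well.negatives_reference / tot_r)
    if lam_r == 0:
        raise ValueError("reference channel has zero occupancy")
    return float(2.0 * lam_t / lam_r)


def genotype_from_copies(copies: float) -> str:
    """Map diploid copies to a duplication genotype class.

    2 -> wild (-/-), 3 -> het (+/-), >= 4 -> hom (+/+); animals carrying two
    multi-copy alleles (e.g. 6 copies) still class as hom. Rounding is
    half-up. Fewer than 2 copies flags a loss.
    """
    if copies < 0:
        raise ValueError("copies must be >= 0")
    c = int(np.floor(copies + 0.5))
    if c < 2:
        return "loss"
    if c == 2:
        return "wild"
    if c == 3:
        return "het"
    return "hom"


def estimate_qpcr(measurement: QpcrMeasurement) -> CopyNumberEstimate:
    _, copies = rq_from_ddct(measurement)
    return CopyNumberEstimate(measurement.sample_id, copies, "qpcr",
                              genotype_from_copies(copies))


def estimate_ddpcr(well: DdpcrWell, sample_id: str = "") -> CopyNumberEstimate:
    copies = ddpcr_copy_number(well)
    return CopyNumberEstimate(sample_id, copies, "ddpcr",
                              genotype_from_copies(copies))
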
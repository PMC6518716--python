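"""Agreement statistics between two wall-deformation measurement methods.

Bland–Altman analysis (bias, SD of paired differences, limits of agreement
bias ± 1.96 SD), the classic pooled-variance two-sample Student's t test,
and Spearman rank correlation.  Statistics are computed at full precision;
the reporting layer rounds to two decimals (four for p values).

The package ships a reference dataset (``data/wall_deformation_study.csv``)
of paired wall-deformation amplitudes for four vessel models, each measured
at four angular positions (anterior/posterior/left/right) in four repeated
probes by the vision-based system and by speckle-tracking echocardiography.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats


class InsufficientPairsError(ValueError):
    """Raised when fewer than two measurement pairs are supplied."""


class DegenerateVarianceError(ValueError):
    """Raised when the pooled variance is zero but the means differ."""


class UndefinedCorrelationError(ValueError):
    """Raised for rank correlation of a constant sample."""


@dataclass
class PairedMeasurements:
    """Equal-length measurements of the same quantities by two methods."""

    a: np.ndarray                  # method A values (mm)
    b: np.ndarray                  # method B values (mm)
    labels: pd.DataFrame | None = None   # patient / position / probe

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("methods must supply equal-length 1-D samples")
        if np.any(~np.isfinite(self.a)) or np.any(~np.isfinite(self.b)):
            raise ValueError("missing pairs are not allowed")

    def __len__(self) -> int:
        return len(self.a)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, col_a: str = "nivbs_mm",
                   col_b: str = "ref_mm") -> "PairedMeasurements":
        return cls(a=df[col_a].to_numpy(), b=df[col_b].to_numpy(),
                   labels=df.drop(columns=[col_a, col_b]))


@dataclass
class AgreementReport:
    """Bland–Altman summary of paired differences."""

    bias: float                    # mean difference (mm)
    sd_diff: float                 # sample SD of differences (mm)
    loa_lower: float               # bias - 1.96 sd
    loa_upper: float               # bias + 1.96 sd
    ci_halfwidth: float            # 1.96 sd
    n_pairs: int

    @property
    def rounded(self) -> dict:
        return {k: round(v, 2) for k, v in
                [("bias", self.bias), ("sd_diff", self.sd_diff),
                 ("loa_lower", self.loa_lower), ("loa_upper", self.loa_upper),
                 ("ci_halfwidth", self.ci_halfwidth)]}

    def to_dict(self) -> dict:
        return {"bias": self.bias, "sd_diff": self.sd_diff,
                "loa_lower": self.loa_lower, "loa_upper": self.loa_upper,
                "ci_halfwidth": self.ci_halfwidth, "n_pairs": self.n_pairs}


def bland_altman(pairs: PairedMeasurements,
                 direction: str = "A_minus_B") -> AgreementReport:
    """Bland–Altman agreement analysis of the paired differences."""
    if direction not in ("A_minus_B", "B_minus_A"):
        raise ValueError("direction must be 'A_minus_B' or 'B_minus_A'")
    if len(pairs) < 2:
        raise InsufficientPairsError("need at least 2 pairs")
    d = pairs.a - pairs.b if direction == "A_minus_B" else pairs.b - pairs.a
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementReport(bias=bias, sd_diff=sd,
                           loa_lower=bias - 1.96 * sd, loa_upper=bias + 1.96 * sd,
                           ci_halfwidth=1.96 * sd, n_pairs=len(d))


def students_t(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided pooled-variance two-sample Student's t test.

    Returns (t, p) with p from the t distribution on n_a + n_b - 2 degrees
    of freedom.  Identical constant samples give (0, 1) by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise DegenerateVarianceError("zero pooled variance with unequal means")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def spearman(sample_a, sample_b) -> float:
    """Spearman's rho: Pearson correlation of mid-ranks (average-rank ties)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need paired samples of length >= 3")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise UndefinedCorrelationError("rank correlation of a constant sample")
    ra = stats.rankdata(a, method="average")
    rb = stats.rankdata(b, method="average")
    return float(np.corrcoef(ra, rb)[0, 1])


def load_study_measurements() -> pd.DataFrame:
    """Paired four-patient wall-deformation dataset shipped with the package.

    Columns: patient, position, probe, nivbs_mm (vision system),
    ref_mm (speckle-tracking echocardiography); 64 rows.
    """
    with resources.files("vesselcam.data").joinpath(
            "wall_deformation_study.csv").open() as fh:
        return pd.read_csv(fh)


def study_pairs(df: pd.DataFrame | None = None,
                position: str | None = None) -> PairedMeasurements:
    """Paired measurements from the study table, optionally one position only."""
    if df is None:
        df = load_study_measurements()
    if position is not None:
        df = df[df["position"] == position]
    return PairedMeasurements.from_frame(df)
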
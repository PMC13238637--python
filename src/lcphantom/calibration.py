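"""The SC-CNR traceability chain.

Two ordinary-least-squares fits make the printed low-contrast phantom
traceable to the contrast-detail reference:

1. on the reference phantom, theoretical subject contrast against measured
   CNR:            SC% = a * CNR_ref + b
2. across phantoms, CNR paired by common hole depth:
                   CNR_lc = c * CNR_ref + d

Substituting (2) into (1) maps any CNR measured on the printed phantom to a
reference-traceable SC-equivalent:  SC% = a * (CNR_lc - d) / c + b.
Threshold depths convert through the phantom's CNR-depth line first, because
observer means fall between discrete hole depths.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "LinearFit",
    "CalibrationModel",
    "fit_linear",
    "fit_sc_cnr",
    "fit_cross_phantom",
    "common_depths",
    "sc_equivalent",
    "threshold_to_sc",
]


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float

    def __call__(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def invert(self, y):
        if self.slope == 0:
            raise ZeroDivisionError("cannot invert a zero-slope fit")
        return (np.asarray(y, dtype=float) - self.intercept) / self.slope


@dataclass(frozen=True)
class CalibrationModel:
    """Per-beam calibration: Eq. SC-CNR fit plus the cross-phantom fit."""

    beam: str
    sc_cnr_fit: LinearFit
    cross_fit: LinearFit

    def __post_init__(self) -> None:
        if self.cross_fit.slope == 0:
            raise ValueError("cross-phantom fit must have a nonzero slope")

    def to_dict(self) -> dict:
        return {
            "beam": self.beam,
            "sc_cnr_fit": asdict(self.sc_cnr_fit),
            "cross_fit": asdict(self.cross_fit),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            beam=d["beam"],
            sc_cnr_fit=LinearFit(**d["sc_cnr_fit"]),
            cross_fit=LinearFit(**d["cross_fit"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def fit_linear(x, y) -> LinearFit:
    """OLS fit with intercept; R^2 = 1 - SS_res/SS_tot (0 for constant y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x values are all equal; fit is degenerate")
    if np.ptp(y) == 0:
        return LinearFit(slope=0.0, intercept=float(y[0]), r_squared=0.0)
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def fit_sc_cnr(sc_values, cnr_values) -> LinearFit:
    """Fit theoretical SC% on measured CNR, paired by hole depth."""
    sc = np.asarray(sc_values, dtype=float)
    cnr = np.asarray(cnr_values, dtype=float)
    if sc.shape != cnr.shape:
        raise ValueError("SC and CNR series must pair one-to-one by depth")
    return fit_linear(cnr, sc)


def common_depths(depths_a, depths_b, decimals: int = 6) -> list[float]:
    """Exact-equality depth intersection (no interpolation), sorted."""
    a = {round(float(d), decimals) for d in depths_a}
    b = {round(float(d), decimals) for d in depths_b}
    return sorted(a & b)


def fit_cross_phantom(cnr_lc: dict, cnr_cdrad: dict) -> LinearFit:
    """Fit LC CNR on reference CNR over the depths present in both phantoms.

    Inputs map hole depth (mm) to measured CNR.
    """
    shared = common_depths(cnr_lc.keys(), cnr_cdrad.keys())
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 common depths, found {len(shared)}: {shared}"
        )
    lc = {round(float(k), 6): v for k, v in cnr_lc.items()}
    cd = {round(float(k), 6): v for k, v in cnr_cdrad.items()}
    x = [cd[d] for d in shared]
    y = [lc[d] for d in shared]
    return fit_linear(x, y)


def sc_equivalent(cnr_lc, model: CalibrationModel):
    """Reference-traceable SC% for a CNR measured on the printed phantom."""
    return model.sc_cnr_fit(model.cross_fit.invert(cnr_lc))


def threshold_to_sc(threshold_depth, cnr_depth_fit: LinearFit, model: CalibrationModel):
    """Map a threshold hole depth to SC% via the CNR-depth line and the chain."""
    return sc_equivalent(cnr_depth_fit(threshold_depth), model)
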
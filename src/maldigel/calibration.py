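"""Internal mass calibration of MALDI peak lists.

Standard peptides spiked into the same sample (by default des-Arg1-bradykinin
and the ACTH 18-39 clip) are located in the raw peak list, and an affine map
``reference = a * observed + b`` is least-squares fitted to the matched pairs
and applied to every peak. Two standards determine the affine map exactly,
which is why a linear model is the natural family for a two-standard
protocol; with more standards the fit is overdetermined and residuals are
reported per reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import chem


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class PeakList:
    """m/z-intensity pairs from one spot, kept sorted ascending by m/z."""

    spot_id: str
    peaks: tuple[Peak, ...]
    calibrated: bool = False

    def __post_init__(self):
        object.__setattr__(
            self, "peaks", tuple(sorted(self.peaks, key=lambda p: p.mz))
        )

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    def __len__(self) -> int:
        return len(self.peaks)


def peak_list(spot_id: str, pairs, calibrated: bool = False) -> PeakList:
    """Build a PeakList from an iterable of (m/z, intensity) pairs."""
    return PeakList(
        spot_id=spot_id,
        peaks=tuple(Peak(mz=float(m), intensity=float(i)) for m, i in pairs),
        calibrated=calibrated,
    )


@dataclass(frozen=True)
class ReferenceStandard:
    """A calibrant peptide; its reference [M+H]+ is computed from sequence
    unless an explicit m/z is given."""

    name: str
    sequence: str | None = None
    mz: float | None = None

    def reference_mz(self) -> float:
        if self.mz is not None:
            if self.mz <= 0:
                raise ValueError(f"reference m/z must be positive, got {self.mz}")
            return self.mz
        if self.sequence is None:
            raise ValueError(f"standard {self.name!r} needs a sequence or an m/z")
        return chem.mz_from_mass(chem.peptide_mass(self.sequence), charge=1)


# The two internal standards of the modelled acquisition protocol.
# Des-Arg1-bradykinin = bradykinin (RPPGFSPFR) minus its N-terminal arginine;
# the ACTH fragment is the 18-39 clip, the usual high-mass MALDI calibrant.
DEFAULT_STANDARDS = (
    ReferenceStandard(name="des-Arg1-bradykinin", sequence="PPGFSPFR"),
    ReferenceStandard(name="ACTH 18-39", sequence="RPVKVYPNGAEDESAEAFPLEF"),
)


class CalibrationError(ValueError):
    """Raised when internal calibration cannot be established."""


@dataclass(frozen=True)
class CalibrationModel:
    """Affine mass-axis correction: calibrated = a * observed + b."""

    a: float
    b: float
    residuals: dict[str, float] = field(default_factory=dict)
    matched_standards: tuple[str, ...] = ()

    def __post_init__(self):
        if not (0.9 < self.a < 1.1):
            raise CalibrationError(
                f"fitted slope {self.a} outside the (0.9, 1.1) sanity band"
            )

    def apply_mz(self, mz: float) -> float:
        return self.a * mz + self.b

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "residuals": dict(self.residuals),
            "matched_standards": list(self.matched_standards),
        }


IDENTITY_MODEL = CalibrationModel(a=1.0, b=0.0)


def match_references(
    peaks: PeakList,
    standards=DEFAULT_STANDARDS,
    coarse_tol: float = 1.0,
) -> tuple[list[tuple[str, float, float]], list[str]]:
    """Pair each standard with its nearest peak within ``coarse_tol`` Da.

    Returns (matches, unmatched) where matches are
    (standard name, observed m/z, reference m/z) triples. Ties between two
    equidistant peaks break deterministically to the lower m/z.
    """
    if coarse_tol <= 0:
        raise ValueError(f"coarse_tol must be positive, got {coarse_tol}")
    mzs = peaks.mz
    matches: list[tuple[str, float, float]] = []
    unmatched: list[str] = []
    for std in standards:
        ref = std.reference_mz()
        if len(mzs) == 0:
            unmatched.append(std.name)
            continue
        dist = np.abs(mzs - ref)
        best = np.flatnonzero(dist == dist.min())[0]  # lowest m/z on ties
        if dist[best] <= coarse_tol:
            matches.append((std.name, float(mzs[best]), ref))
        else:
            unmatched.append(std.name)
    return matches, unmatched


def fit_calibration(pairs: list[tuple[float, float]], names=None) -> CalibrationModel:
    """Least-squares affine fit of reference = a * observed + b.

    ``pairs`` are (observed, reference) m/z tuples; with exactly two pairs the
    fit interpolates both points (residuals zero).
    """
    if len(pairs) < 2:
        raise CalibrationError(
            f"internal calibration needs >= 2 matched standards, got {len(pairs)}"
        )
    obs = np.array([p[0] for p in pairs])
    ref = np.array([p[1] for p in pairs])
    if len(np.unique(obs)) != len(obs):
        raise CalibrationError("duplicate observed m/z among calibration pairs")
    # closed-form normal equations for the 2-parameter fit
    A = np.vstack([obs, np.ones_like(obs)]).T
    (a, b), *_ = np.linalg.lstsq(A, ref, rcond=None)
    fitted = a * obs + b
    names = names or [f"ref@{r:.4f}" for r in ref]
    residuals = {n: float(r - f) for n, r, f in zip(names, ref, fitted)}
    return CalibrationModel(
        a=float(a), b=float(b), residuals=residuals, matched_standards=tuple(names)
    )


def calibrate(
    peaks: PeakList,
    standards=DEFAULT_STANDARDS,
    coarse_tol: float = 1.0,
) -> tuple[PeakList, CalibrationModel]:
    """Match standards, fit the affine model, and apply it. One-stop helper."""
    matches, unmatched = match_references(peaks, standards, coarse_tol)
    if len(matches) < 2:
        raise CalibrationError(
            f"only {len(matches)} standard(s) matched (unmatched: {unmatched}); "
            "internal calibration impossible"
        )
    model = fit_calibration(
        [(obs, ref) for _, obs, ref in matches], names=[n for n, _, _ in matches]
    )
    return apply_calibration(peaks, model), model


def apply_calibration(
    peaks: PeakList, model: CalibrationModel, force: bool = False
) -> PeakList:
    """Map every m/z through the affine model; intensities are untouched."""
    if peaks.calibrated and not force:
        raise ValueError(
            f"peak list {peaks.spot_id!r} is already calibrated (pass force=True to re-calibrate)"
        )
    new = tuple(
        replace(p, mz=model.apply_mz(p.mz)) for p in peaks.peaks
    )
    return PeakList(spot_id=peaks.spot_id, peaks=new, calibrated=True)
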
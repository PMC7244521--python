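"""Sign-segmented field–energy regression and equivalent-atomic-charge models.

The QM/MM interaction energy of the CO probe is, statistically, linear in
the electric field along the bond — but with a different slope for
positive and negative fields, reflecting the two antiparallel orientational
states the probe adopts.  Partitioning the samples by field sign and
fitting each segment by ordinary least squares gives the two slopes k1
(positive fields) and k2 (negative fields); their unsigned ratio |k1|/|k2|
tracks the population ratio of the two states.

Each slope maps onto a constant-moment dipole, E = μ·F with μ = q·l: the
"equivalent atomic charge" (EAC) q = −slope / (K_COUL · l) is the O-atom
charge of a neutral C^−q O^+q probe whose dipole reproduces the observed
linear response.  Under a positive field the O carries a positive charge
(q_pos > 0) and under a negative field a negative one (q_neg < 0); both
branches are stabilizing.  Replacing a low-level method's EAC energies with
a high-level method's, frame by frame, corrects the low-level interaction
energies toward the high-level target — an inexpensive surrogate for the
missing electron-correlation contribution.

The module-level functions implement the individual operations; the
:class:`SegmentedStarkModel` / :class:`SegmentedStarkResults` pair wraps
them in a fit/results workflow with a bootstrap confidence interval on
k1/k2 and a printable summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field as dataclass_field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import K_COUL, DEFAULT_BOND_LENGTH


@dataclass(frozen=True)
class SegmentedFit:
    """OLS results on the two field-sign segments.

    Slopes are in kcal/mol per (e/Å²) and signed; k1 is the positive-field
    slope, k2 the negative-field slope.  n_zero counts excluded
    exactly-zero-field samples.
    """

    slope_pos: float
    intercept_pos: float
    slope_neg: float
    intercept_neg: float
    n_pos: int
    n_neg: int
    r2_pos: float
    r2_neg: float
    n_zero: int = 0


@dataclass(frozen=True)
class EACModel:
    """Piecewise constant-dipole model of the probe's field response.

    q_pos is the O-atom equivalent charge active for field > 0 (positive
    for a C⁻O⁺ state), q_neg the charge active for field < 0 (negative for
    C⁺O⁻).  Energies are −K_COUL · q_active · F · l, zero at F = 0 and
    continuous there.
    """

    q_pos: float
    q_neg: float
    bond_length: float = DEFAULT_BOND_LENGTH
    method_label: str = ""

    def __post_init__(self):
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")


@dataclass(frozen=True)
class AgreementStats:
    """Pearson R² and mean unsigned error between two energy series."""

    r_squared: float
    mue: float
    n: int


def _ols_segment(x: np.ndarray, y: np.ndarray, side: str):
    if len(x) < 2:
        raise ValueError(
            f"need at least 2 samples with field {side} 0 for the segmented fit "
            f"(got {len(x)})"
        )
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res <= 1e-20 else 0.0
    else:
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return float(slope), float(intercept), r2


def segmented_fit(field, energy) -> SegmentedFit:
    """Independent free-intercept OLS on the field>0 and field<0 segments.

    Samples with field exactly 0 are excluded (and counted in ``n_zero``);
    either segment with fewer than 2 samples is an error naming the side.
    """
    f = np.asarray(field, dtype=float)
    e = np.asarray(energy, dtype=float)
    if f.shape != e.shape or f.ndim != 1:
        raise ValueError("field and energy must be 1-D of equal length")
    pos = f > 0
    neg = f < 0
    sp, ip, r2p = _ols_segment(f[pos], e[pos], ">")
    sn, in_, r2n = _ols_segment(f[neg], e[neg], "<")
    return SegmentedFit(
        slope_pos=sp, intercept_pos=ip,
        slope_neg=sn, intercept_neg=in_,
        n_pos=int(pos.sum()), n_neg=int(neg.sum()),
        r2_pos=r2p, r2_neg=r2n,
        n_zero=int(len(f) - pos.sum() - neg.sum()),
    )


def slope_ratio(fit: SegmentedFit) -> float:
    """Unsigned slope ratio |k1|/|k2| (dimensionless)."""
    if fit.slope_neg == 0.0:
        raise ValueError("negative-field slope is zero; ratio undefined")
    return abs(fit.slope_pos) / abs(fit.slope_neg)


def eac_from_slope(slope: float, bond_length: float = DEFAULT_BOND_LENGTH) -> float:
    """Equivalent atomic charge (O-atom, e) from a field–energy slope.

    q = −slope / (K_COUL · l): a stabilizing (negative) positive-field
    slope yields q_pos > 0, the C⁻O⁺ state.
    """
    if bond_length <= 0:
        raise ValueError("bond_length must be positive")
    return -slope / (K_COUL * bond_length)


def eac_from_fit(
    fit: SegmentedFit,
    bond_length: float = DEFAULT_BOND_LENGTH,
    method_label: str = "",
) -> EACModel:
    """Derive the piecewise EAC model from a segmented fit (slopes only)."""
    return EACModel(
        q_pos=eac_from_slope(fit.slope_pos, bond_length),
        q_neg=eac_from_slope(fit.slope_neg, bond_length),
        bond_length=bond_length,
        method_label=method_label,
    )


def eac_energy(model: EACModel, field, bond_length=None):
    """Piecewise constant-dipole energy, kcal/mol.

    Uses q_pos for field > 0, q_neg for field < 0 and 0 at field = 0
    (continuous).  `bond_length` may be a per-frame array to override the
    model's fixed constant.
    """
    f = np.asarray(field, dtype=float)
    length = model.bond_length if bond_length is None else np.asarray(bond_length, dtype=float)
    q = np.where(f > 0, model.q_pos, np.where(f < 0, model.q_neg, 0.0))
    out = -K_COUL * q * f * length
    return float(out) if out.ndim == 0 else out


def correct_energies(
    e_low,
    fields,
    model_low: EACModel,
    model_high: EACModel,
    bond_lengths=None,
):
    """EAC-based correction of low-level energies toward a high-level target.

    Per frame: E_corrected = E_low − E_EAC(low, F) + E_EAC(high, F).  The
    low-level model's linear response is subtracted out and the high-level
    one substituted, emulating the missing electron-correlation
    contribution to the interaction energy.
    """
    e_low = np.asarray(e_low, dtype=float)
    f = np.asarray(fields, dtype=float)
    if e_low.shape != f.shape:
        raise ValueError("e_low and fields must have matching lengths")
    if model_low == model_high:
        return e_low.copy()  # exact identity, no float round-trip
    return (
        e_low
        - eac_energy(model_low, f, bond_lengths)
        + eac_energy(model_high, f, bond_lengths)
    )


def agreement_stats(series_a, series_b) -> AgreementStats:
    """Squared Pearson correlation and mean unsigned error of two series.

    R² alone cannot certify agreement (it is invariant to affine maps,
    including sign flips), so the MUE is always reported alongside.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D series with n >= 2")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise ValueError("zero variance in input series; R² undefined")
    mue = float(np.mean(np.abs(a - b)))
    if np.allclose(a, b, rtol=0.0, atol=0.0):
        r2 = 1.0  # identical series: pearsonr would still give 1, shortcut is exact
    else:
        r2 = float(stats.pearsonr(a, b).statistic ** 2)
    return AgreementStats(r_squared=r2, mue=mue, n=len(a))


# ---------------------------------------------------------------------------
# Model / Results workflow
# ---------------------------------------------------------------------------

class SegmentedStarkModel:
    """Sign-segmented linear model of interaction energy versus bond field.

    Parameters
    ----------
    field : array-like
        Signed electric field along the CO bond per frame, e/Å².
    energy : array-like
        Electrostatic interaction energy per frame, kcal/mol.
    method_label : str
        Free-text label of the method that produced the energies
        (e.g. "HF", "B3LYP", "MP2").
    bond_length : float
        Bond length used when converting slopes to equivalent charges, Å.

    Examples
    --------
    >>> model = SegmentedStarkModel(field, energy, method_label="MP2")
    >>> res = model.fit(n_boot=1000, seed=0)
    >>> print(res.summary())
    """

    def __init__(self, field, energy, method_label: str = "",
                 bond_length: float = DEFAULT_BOND_LENGTH):
        self.field = np.asarray(field, dtype=float)
        self.energy = np.asarray(energy, dtype=float)
        if self.field.shape != self.energy.shape or self.field.ndim != 1:
            raise ValueError("field and energy must be 1-D of equal length")
        self.method_label = method_label
        self.bond_length = float(bond_length)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, field_col: str = "field",
                       energy_col: str = "E_EI", method_label: str = "",
                       bond_length: float = DEFAULT_BOND_LENGTH,
                       ) -> "SegmentedStarkModel":
        missing = {field_col, energy_col} - set(df.columns)
        if missing:
            raise ValueError(f"dataframe missing columns: {sorted(missing)}")
        return cls(df[field_col].to_numpy(), df[energy_col].to_numpy(),
                   method_label=method_label, bond_length=bond_length)

    def fit(self, n_boot: int = 1000, seed: int | None = None,
            ci_level: float = 0.95) -> "SegmentedStarkResults":
        """Fit both segments; attach a bootstrap CI to the slope ratio.

        The bootstrap is stratified by field sign (resampling within each
        segment) so every resample keeps both segments populated.
        """
        fit = segmented_fit(self.field, self.energy)
        ratio = slope_ratio(fit)
        ci = (np.nan, np.nan)
        boot = np.empty(0)
        if n_boot > 0:
            rng = np.random.default_rng(seed)
            pos = np.flatnonzero(self.field > 0)
            neg = np.flatnonzero(self.field < 0)
            boot = np.empty(n_boot)
            for b in range(n_boot):
                idx = np.concatenate([
                    rng.choice(pos, size=len(pos), replace=True),
                    rng.choice(neg, size=len(neg), replace=True),
                ])
                boot[b] = slope_ratio(
                    segmented_fit(self.field[idx], self.energy[idx])
                )
            alpha = 1.0 - ci_level
            ci = tuple(np.quantile(boot, [alpha / 2, 1 - alpha / 2]))
        return SegmentedStarkResults(
            model=self, fit=fit, ratio=ratio, ratio_ci=ci,
            bootstrap_ratios=boot, n_boot=n_boot, seed=seed,
        )


@dataclass(frozen=True)
class SegmentedStarkResults:
    """Results of a :class:`SegmentedStarkModel` fit."""

    model: SegmentedStarkModel
    fit: SegmentedFit
    ratio: float
    ratio_ci: tuple
    bootstrap_ratios: np.ndarray = dataclass_field(repr=False, default=None)  # type: ignore[assignment]
    n_boot: int = 0
    seed: int | None = None

    @property
    def eac(self) -> EACModel:
        """Piecewise equivalent-atomic-charge model derived from the slopes."""
        return eac_from_fit(self.fit, self.model.bond_length,
                            self.model.method_label)

    def summary(self) -> str:
        f = self.fit
        eac = self.eac
        lines = [
            "Segmented field-energy fit"
            + (f" [{self.model.method_label}]" if self.model.method_label else ""),
            "=" * 58,
            f"{'segment':<12}{'n':>7}{'slope':>14}{'intercept':>12}{'R2':>9}",
            f"{'field > 0':<12}{f.n_pos:>7}{f.slope_pos:>14.4f}"
            f"{f.intercept_pos:>12.4f}{f.r2_pos:>9.4f}",
            f"{'field < 0':<12}{f.n_neg:>7}{f.slope_neg:>14.4f}"
            f"{f.intercept_neg:>12.4f}{f.r2_neg:>9.4f}",
            "-" * 58,
            f"|k1|/|k2| = {self.ratio:.4f}"
            + (
                f"   (95% bootstrap CI [{self.ratio_ci[0]:.4f}, "
                f"{self.ratio_ci[1]:.4f}], B={self.n_boot})"
                if self.n_boot > 0 else ""
            ),
            f"EAC (l = {eac.bond_length:.2f} A): "
            f"q_pos = {eac.q_pos:+.4f} e, q_neg = {eac.q_neg:+.4f} e",
        ]
        if f.n_zero:
            lines.append(f"excluded {f.n_zero} samples with field exactly 0")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = asdict(self.fit)
        eac = self.eac
        d.update(
            method_label=self.model.method_label,
            bond_length=self.model.bond_length,
            q_pos=eac.q_pos, q_neg=eac.q_neg,
            slope_ratio=self.ratio,
            ratio_ci_low=float(self.ratio_ci[0]),
            ratio_ci_high=float(self.ratio_ci[1]),
            n_boot=self.n_boot, seed=self.seed,
        )
        return d

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def plot(self, ax=None):
        """Scatter of the samples with the two fitted segment lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        f, e = self.model.field, self.model.energy
        ax.plot(f, e, ".", ms=2, alpha=0.4, color="0.4")
        for sl, ic, mask, color, lab in (
            (self.fit.slope_pos, self.fit.intercept_pos, f > 0, "tab:green", "k1"),
            (self.fit.slope_neg, self.fit.intercept_neg, f < 0, "tab:blue", "k2"),
        ):
            if mask.any():
                grid = np.linspace(0.0, f[mask].max() if lab == "k1" else f[mask].min(), 50)
                ax.plot(grid, sl * grid + ic, color=color, label=lab)
        ax.axvline(0.0, color="0.8", lw=0.8)
        ax.set_xlabel("field along CO bond (e/Å²)")
        ax.set_ylabel("interaction energy (kcal/mol)")
        ax.legend()
        return ax
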
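"""Point-charge electrostatics around a diatomic CO probe.

The environment (protein + heme + solvent) is represented as bare point
charges.  The electrostatic potential at the probe C and O centres is the
Coulomb sum over all environment charges, and the mean electric field along
the bond is the potential difference divided by the bond length.  The sign
convention is physical: a configuration with higher potential at C than at
O gives a positive field, i.e. the positive field direction points from C
toward O.

Two classical interaction-energy forms are provided: the generic
point-charge energy for arbitrary probe charges, and the polarizable-probe
energy in which the O charge responds linearly to the field (the C charge
mirrors it so the probe stays neutral), which makes the energy an exact
quadratic in the field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .constants import K_COUL, MIN_SEPARATION


class SingularityError(ValueError):
    """An environment charge sits unphysically close to an evaluation point."""


@dataclass(frozen=True)
class COProbe:
    """The diatomic probe: C and O positions in Å.

    The bond vector points from C to O.  Bond lengths outside the
    physically plausible CO window [0.8, 1.6] Å trigger a warning but are
    accepted, so slightly pathological trajectory frames do not abort an
    analysis.
    """

    c_position: np.ndarray
    o_position: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.c_position, dtype=float)
        o = np.asarray(self.o_position, dtype=float)
        if c.shape != (3,) or o.shape != (3,):
            raise ValueError("probe positions must be 3-vectors")
        if not (np.all(np.isfinite(c)) and np.all(np.isfinite(o))):
            raise ValueError("probe positions must be finite")
        object.__setattr__(self, "c_position", c)
        object.__setattr__(self, "o_position", o)
        length = float(np.linalg.norm(o - c))
        if length <= 0.0:
            raise ValueError("probe C and O positions coincide")
        if not 0.8 <= length <= 1.6:
            warnings.warn(
                f"CO bond length {length:.3f} Å outside plausible [0.8, 1.6] Å",
                stacklevel=2,
            )

    @property
    def bond_vector(self) -> np.ndarray:
        return self.o_position - self.c_position

    @property
    def bond_length(self) -> float:
        return float(np.linalg.norm(self.bond_vector))


@dataclass(frozen=True)
class ChargeEnvironment:
    """Ordered collection of environment point charges.

    positions : (n, 3) float array, Å
    charges : (n,) float array, elementary charge e
    residue_indices, atom_indices : (n,) int labels (bookkeeping only)
    """

    positions: np.ndarray
    charges: np.ndarray
    residue_indices: np.ndarray = dataclass_field(default=None)  # type: ignore[assignment]
    atom_indices: np.ndarray = dataclass_field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.size == 0:
            pos = np.empty((0, 3))
        q = np.atleast_1d(np.asarray(self.charges, dtype=float))
        if pos.shape != (len(q), 3):
            raise ValueError(
                f"positions {pos.shape} inconsistent with {len(q)} charges"
            )
        if not np.all(np.isfinite(pos)) or not np.all(np.isfinite(q)):
            raise ValueError("environment positions and charges must be finite")
        res = self.residue_indices
        atm = self.atom_indices
        res = np.arange(len(q)) if res is None else np.asarray(res, dtype=int)
        atm = np.arange(len(q)) if atm is None else np.asarray(atm, dtype=int)
        if len(res) != len(q) or len(atm) != len(q):
            raise ValueError("index labels must match the number of charges")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "charges", q)
        object.__setattr__(self, "residue_indices", res)
        object.__setattr__(self, "atom_indices", atm)

    def __len__(self) -> int:
        return len(self.charges)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def __add__(self, other: "ChargeEnvironment") -> "ChargeEnvironment":
        """Union of two environments (superposition of their charges)."""
        return ChargeEnvironment(
            np.vstack([self.positions, other.positions]),
            np.concatenate([self.charges, other.charges]),
            np.concatenate([self.residue_indices, other.residue_indices]),
            np.concatenate([self.atom_indices, other.atom_indices]),
        )


@dataclass(frozen=True)
class FieldSample:
    """Signed mean electric field along the CO bond for one frame.

    Units e/Å²; positive direction from C toward O.
    """

    frame_index: int
    field: float
    bond_length: float

    def __post_init__(self):
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        if not np.isfinite(self.field):
            raise ValueError("field must be finite")


@dataclass(frozen=True)
class PolarizableChargeModel:
    """Linear response of the probe O ESP charge to the bond field.

    q_O(F) = alpha * F + q0, with alpha in e per (e/Å²) and q0 the
    zero-field O charge (small for gas-phase CO).  The C charge is −q_O so
    the probe stays neutral.
    """

    alpha: float
    q0: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.alpha) and np.isfinite(self.q0)):
            raise ValueError("alpha and q0 must be finite")


def _distances(env: ChargeEnvironment, point: np.ndarray) -> np.ndarray:
    point = np.asarray(point, dtype=float)
    if point.shape != (3,):
        raise ValueError("evaluation point must be a 3-vector")
    return np.linalg.norm(env.positions - point, axis=1)


def potential_at_point(
    env: ChargeEnvironment,
    point: np.ndarray,
    eps_eff: float = 1.0,
    cutoff: float | None = None,
) -> float:
    """Bare Coulomb potential Σ q_j / |r − r_j| at `point`, in e/Å.

    eps_eff is a dimensionless effective dielectric divisor (1.0 with
    explicit solvent).  An optional radial cutoff drops charges beyond
    `cutoff` Å, mirroring the finite electrostatic cutoff of the
    simulations that produce real trajectories; the default is no cutoff
    (the sum runs over all residues).
    """
    if eps_eff <= 0:
        raise ValueError("eps_eff must be positive")
    if len(env) == 0:
        return 0.0
    d = _distances(env, point)
    if cutoff is not None:
        mask = d <= cutoff
        d, q = d[mask], env.charges[mask]
    else:
        q = env.charges
    if d.size == 0:
        return 0.0
    dmin = d.min()
    if dmin < MIN_SEPARATION:
        raise SingularityError(
            f"environment charge at {dmin:.3f} Å from evaluation point "
            f"(< {MIN_SEPARATION} Å guard)"
        )
    return float(np.sum(q / d) / eps_eff)


def field_along_bond(
    env: ChargeEnvironment,
    probe: COProbe,
    eps_eff: float = 1.0,
    frame_index: int = 0,
    cutoff: float | None = None,
) -> FieldSample:
    """Mean electric field along the CO bond, (φ(C) − φ(O)) / |r_CO|, e/Å².

    Positive when the potential at C exceeds that at O, i.e. when the field
    points from C toward O.
    """
    phi_c = potential_at_point(env, probe.c_position, eps_eff, cutoff)
    phi_o = potential_at_point(env, probe.o_position, eps_eff, cutoff)
    return FieldSample(
        frame_index=frame_index,
        field=(phi_c - phi_o) / probe.bond_length,
        bond_length=probe.bond_length,
    )


def polarizable_charge(field: float, model: PolarizableChargeModel) -> float:
    """O-atom ESP charge under the linear-response model, q_O = αF + q0 (e)."""
    return model.alpha * field + model.q0


def classical_interaction_energy(
    env: ChargeEnvironment,
    probe: COProbe,
    q_c: float,
    q_o: float,
    eps_eff: float = 1.0,
    cutoff: float | None = None,
) -> float:
    """Point-charge interaction energy of the probe with the environment.

    energy = K_COUL · (q_C·φ(r_C) + q_O·φ(r_O)), kcal/mol.  The probe
    charges are free parameters; the neutral-probe convention q_C = −q_O is
    the caller's choice (see :func:`polarization_energy` for the
    self-consistent neutral polarizable probe).
    """
    phi_c = potential_at_point(env, probe.c_position, eps_eff, cutoff)
    phi_o = potential_at_point(env, probe.o_position, eps_eff, cutoff)
    return K_COUL * (q_c * phi_c + q_o * phi_o)


def polarization_energy(
    field: float,
    model: PolarizableChargeModel,
    bond_length: float,
) -> float:
    """Energy of the field-polarized neutral probe in a uniform field.

    energy = −K_COUL · (αF + q0) · F · l, kcal/mol.  For q0 = 0 this is an
    exact even quadratic in the field (stabilizing for α > 0), with its
    extremum at F = −q0/(2α) in general.  This is the bare interaction form
    (no ½ self-polarization work term).
    """
    if bond_length <= 0:
        raise ValueError("bond_length must be positive")
    field = np.asarray(field, dtype=float)
    out = -K_COUL * (model.alpha * field + model.q0) * field * bond_length
    return float(out) if out.ndim == 0 else out
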
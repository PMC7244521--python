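"""File formats: PQR/PDB structures in, CSV/JSON tables out.

Charge-annotated structures are read from PQR (whitespace-separated ATOM /
HETATM records with per-atom charge and radius; the radius is ignored).
Structure parsing is delegated to MDAnalysis, with a cheap pre-scan that
turns malformed records into errors carrying the offending line number.
Tables are CSV with mandated headers, floats written with 10 significant
digits so byte-level determinism is testable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .electrostatics import ChargeEnvironment, COProbe

FLOAT_FORMAT = "%.10g"


class PQRFormatError(ValueError):
    """A PQR record that cannot be parsed, with its line number."""


def _prescan_pqr(path):
    """Validate ATOM/HETATM records line by line before handing to MDAnalysis."""
    n_atoms = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            parts = line.split()
            # name, serial, atom name, residue name, [chain], resid, x y z, q, r
            if len(parts) < 10:
                raise PQRFormatError(
                    f"{path}, line {lineno}: expected >= 10 whitespace-separated "
                    f"fields in ATOM record, got {len(parts)}"
                )
            try:
                [float(v) for v in parts[-5:]]
            except ValueError as exc:
                raise PQRFormatError(
                    f"{path}, line {lineno}: trailing coordinate/charge/radius "
                    f"fields are not numeric ({exc})"
                ) from None
            n_atoms += 1
    if n_atoms == 0:
        raise PQRFormatError(f"{path}: no ATOM/HETATM records found")
    return n_atoms


def read_pqr(path) -> ChargeEnvironment:
    """Load a PQR file into a charge environment.

    Both the aligned-column and single-space PQR dialects parse
    identically (fields are whitespace-delimited).
    """
    import MDAnalysis as mda

    _prescan_pqr(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MDAnalysis guessing chatter
        u = mda.Universe(str(path))
    try:
        charges = u.atoms.charges
    except Exception:
        raise PQRFormatError(f"{path}: missing charge column") from None
    return ChargeEnvironment(
        positions=u.atoms.positions.astype(float),
        charges=np.asarray(charges, dtype=float),
        residue_indices=u.atoms.resids.astype(int),
        atom_indices=np.arange(len(u.atoms)),
    )


def read_probe_frame(path, ligand_resname: str = "CO", c_name: str = "C",
                     o_name: str = "O", fe_name: str = "FE"):
    """Extract (probe, fe_position, environment) from a PQR/PDB frame.

    The probe C and O are located by atom name within the ligand residue,
    the iron by atom name anywhere; every atom other than the probe pair
    forms the charge environment (zero charges for a plain PDB).
    """
    import MDAnalysis as mda

    if str(path).lower().endswith(".pqr"):
        _prescan_pqr(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    lig = u.select_atoms(f"resname {ligand_resname}")
    c_sel = lig.select_atoms(f"name {c_name}")
    o_sel = lig.select_atoms(f"name {o_name}")
    fe_sel = u.select_atoms(f"name {fe_name}")
    if len(c_sel) != 1 or len(o_sel) != 1:
        raise PQRFormatError(
            f"{path}: expected exactly one {c_name} and one {o_name} atom in "
            f"residue {ligand_resname} (got {len(c_sel)}/{len(o_sel)})"
        )
    probe = COProbe(c_sel.positions[0].astype(float),
                    o_sel.positions[0].astype(float))
    fe_position = fe_sel.positions[0].astype(float) if len(fe_sel) == 1 else None
    env_atoms = u.atoms - c_sel - o_sel
    try:
        charges = np.asarray(env_atoms.charges, dtype=float)
    except Exception:
        charges = np.zeros(len(env_atoms))
    env = ChargeEnvironment(
        positions=env_atoms.positions.astype(float),
        charges=charges,
        residue_indices=env_atoms.resids.astype(int),
        atom_indices=np.arange(len(env_atoms)),
    )
    return probe, fe_position, env


def write_pqr(path, env: ChargeEnvironment, probe: COProbe | None = None,
              fe_position=None, radius: float = 1.5) -> None:
    """Write a charge environment (plus optional CO probe and Fe) as PQR.

    Environment atoms are emitted as single-atom ENV residues; the probe as
    a CO residue with zero charges (its charges are model outputs, not
    inputs) and the iron as a HEM FE record.
    """
    def record(serial, name, resname, resid, pos, q, r):
        return (f"ATOM  {serial:>5d} {name:<4s} {resname:<4s}{resid:>5d}    "
                f"{pos[0]:10.4f} {pos[1]:10.4f} {pos[2]:10.4f} "
                f"{q:9.5f} {r:7.4f}\n")

    with open(path, "w") as fh:
        serial = 1
        if probe is not None:
            fh.write(record(serial, "C", "CO", 1, probe.c_position, 0.0, radius))
            serial += 1
            fh.write(record(serial, "O", "CO", 1, probe.o_position, 0.0, radius))
            serial += 1
        if fe_position is not None:
            fh.write(record(serial, "FE", "HEM", 2, fe_position, 0.0, radius))
            serial += 1
        for i in range(len(env)):
            fh.write(record(serial, "Q", "ENV", int(env.residue_indices[i]) + 3,
                            env.positions[i], float(env.charges[i]), radius))
            serial += 1
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    """CSV with 10-significant-digit floats (determinism-testable)."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _read_csv(path, required: set) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_field_table(path) -> pd.DataFrame:
    """frame, field, bond_length (+ any extra columns such as q_esp)."""
    return _read_csv(path, {"frame", "field", "bond_length"})


def read_energy_table(path) -> pd.DataFrame:
    """frame, method, E_total, E_self; E_EI is recomputed, never trusted."""
    from .decomposition import add_interaction_energy

    df = _read_csv(path, {"frame", "method", "E_total", "E_self"})
    return add_interaction_energy(df.drop(columns=["E_EI"], errors="ignore"))


def read_angle_table(path) -> pd.DataFrame:
    """frame, angle_deg (+ optional state column, ignored on read)."""
    return _read_csv(path, {"frame", "angle_deg"})
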
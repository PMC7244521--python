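"""End-to-end analysis pipeline and its configuration.

Chains the stages: (simulate | load) field/energy/angle tables → recompute
interaction energies → sign-segmented fits and EAC models per method →
EAC-based correction of the low-level methods toward the high-level target
with agreement scoring → B-state classification — and writes every
artifact (CSV/JSON) plus a summary mirroring the method / k1/k2 / B1/B2
table layout.  Every output is stamped with the seed and a hash of the
configuration, and a rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict, field as dataclass_field
from pathlib import Path

import numpy as np

from . import io as cio
from .constants import DEFAULT_BOND_LENGTH
from .decomposition import detrend_on_bond_length
from .eac import SegmentedStarkModel, agreement_stats, correct_energies
from .geometry import B_STATE_THRESHOLD, angle_histogram, classify_state, state_ratio
from .synthetic import GeneratorTruth, generate_angle_series, generate_field_energy_table


class PipelineError(RuntimeError):
    """A stage-level failure; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Either the three input table paths are given (real data) or they are
    left None and the synthetic generator produces them (n_frames frames at
    the stated-world defaults) — exactly one of the two modes per run.
    """

    outdir: str = "costark_out"
    seed: int = 0
    n_frames: int = 10000
    field_table: str | None = None
    energy_table: str | None = None
    angle_table: str | None = None
    eps_eff: float = 1.0
    bond_length: float = DEFAULT_BOND_LENGTH
    per_frame_bond_length: bool = False
    detrend: bool = False
    threshold_deg: float = B_STATE_THRESHOLD
    n_boot: int = 1000
    high_method: str = "MP2"
    bin_width_deg: float = 2.0

    def __post_init__(self):
        paths = [self.field_table, self.energy_table]
        if (paths[0] is None) != (paths[1] is None):
            raise ValueError(
                "field_table and energy_table must be given together "
                "(or both omitted for generator mode)"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        # hash the scientific parameters only, not the output location
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        text = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    """Paths of every artifact plus the in-memory summary dictionary."""

    outdir: Path
    summary: dict
    artifacts: dict = dataclass_field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run every stage; on failure, remove partial outputs and name the stage."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit_table(df, name):
        path = outdir / name
        cio.write_table(df, path)
        written.append(path)
        return path

    def emit_json(obj, name):
        path = outdir / name
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(path)
        return path

    stamp = {"seed": config.seed, "config_hash": config.hash()}
    artifacts: dict = {}
    try:
        stage = "simulate"
        if config.field_table is None:
            rng = np.random.default_rng(config.seed)
            truth = GeneratorTruth(bond_length_mean=config.bond_length)
            field_df, energy_df = generate_field_energy_table(
                truth, config.n_frames, rng)
            angle_df = generate_angle_series(truth, config.n_frames, rng)
            artifacts["field_table"] = emit_table(field_df, "fields.csv")
            artifacts["energy_table"] = emit_table(energy_df, "energies_raw.csv")
            artifacts["angle_table"] = emit_table(angle_df, "angles.csv")
            # consume the written tables so the composed pipeline is
            # bit-for-bit equal to running the standalone stages on them
            field_df = cio.read_field_table(artifacts["field_table"])
            energy_df = cio.read_energy_table(artifacts["energy_table"])
            angle_df = cio.read_angle_table(artifacts["angle_table"])
        else:
            field_df = cio.read_field_table(config.field_table)
            energy_df = cio.read_energy_table(config.energy_table)
            angle_df = (cio.read_angle_table(config.angle_table)
                        if config.angle_table else None)

        stage = "decompose"
        from .decomposition import add_interaction_energy
        if "E_EI" not in energy_df.columns:
            energy_df = add_interaction_energy(energy_df)
        artifacts["interaction_table"] = emit_table(energy_df, "energies_ei.csv")

        stage = "fit-eac"
        fields = field_df["field"].to_numpy()
        lengths = field_df["bond_length"].to_numpy()
        methods = list(dict.fromkeys(energy_df["method"]))
        results = {}
        detrend_slopes = {}
        for label in methods:
            sub = energy_df[energy_df["method"] == label]
            e_ei = sub.set_index("frame").loc[field_df["frame"], "E_EI"].to_numpy()
            if config.detrend:
                det = detrend_on_bond_length(e_ei, lengths)
                e_ei = det.values
                detrend_slopes[label] = det.detrend_slope
            model = SegmentedStarkModel(fields, e_ei, method_label=label,
                                        bond_length=config.bond_length)
            results[label] = model.fit(n_boot=config.n_boot, seed=config.seed)
        fit_payload = {lab: res.to_dict() for lab, res in results.items()}
        if detrend_slopes:
            for lab, sl in detrend_slopes.items():
                fit_payload[lab]["detrend_slope"] = sl
        artifacts["eac_json"] = emit_json({**stamp, "fits": fit_payload},
                                          "eac_fits.json")

        stage = "correct"
        agreement = {}
        if config.high_method in results and len(results) > 1:
            high_res = results[config.high_method]
            high_e = (energy_df[energy_df["method"] == config.high_method]
                      .set_index("frame").loc[field_df["frame"], "E_EI"]
                      .to_numpy())
            per_frame_l = lengths if config.per_frame_bond_length else None
            corrected_cols = {"frame": field_df["frame"].to_numpy(),
                              "field": fields}
            for label in methods:
                if label == config.high_method:
                    continue
                low_e = (energy_df[energy_df["method"] == label]
                         .set_index("frame").loc[field_df["frame"], "E_EI"]
                         .to_numpy())
                corr = correct_energies(low_e, fields, results[label].eac,
                                        high_res.eac, per_frame_l)
                corrected_cols[f"E_corrected_{label}"] = corr
                raw = agreement_stats(low_e, high_e)
                cor = agreement_stats(corr, high_e)
                agreement[label] = {
                    "raw_r2": raw.r_squared, "raw_mue": raw.mue,
                    "corrected_r2": cor.r_squared, "corrected_mue": cor.mue,
                    "n": cor.n, "target": config.high_method,
                }
            import pandas as pd
            artifacts["corrected_table"] = emit_table(
                pd.DataFrame(corrected_cols), "energies_corrected.csv")
            artifacts["agreement_json"] = emit_json({**stamp, **agreement},
                                                    "agreement.json")

        stage = "classify"
        states = None
        if angle_df is not None:
            angles = angle_df["angle_deg"].to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                states = state_ratio(angles, config.threshold_deg)
            edges, density = angle_histogram(angles, config.bin_width_deg)
            import pandas as pd
            artifacts["histogram_table"] = emit_table(
                pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:],
                              "density": density}),
                "angle_histogram.csv")
            out_angles = angle_df.copy()
            out_angles["state"] = classify_state(angles, config.threshold_deg)
            artifacts["state_table"] = emit_table(out_angles, "angle_states.csv")

        stage = "report"
        summary = {
            **stamp,
            "methods": {
                lab: {
                    "k1": res.fit.slope_pos,
                    "k2": res.fit.slope_neg,
                    "k1_over_k2": res.ratio,
                    "ratio_ci": [float(res.ratio_ci[0]), float(res.ratio_ci[1])],
                    "q_pos": res.eac.q_pos,
                    "q_neg": res.eac.q_neg,
                }
                for lab, res in results.items()
            },
            "agreement": agreement,
        }
        if states is not None:
            summary["b_states"] = {
                "n_b1": states.n_b1, "n_b2": states.n_b2,
                "b1_over_b2": (states.n_b1 / states.n_b2
                               if states.n_b2 else None),
            }
        artifacts["summary_json"] = emit_json(summary, "summary.json")
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc

    return PipelineReport(outdir=outdir, summary=summary, artifacts=artifacts)
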
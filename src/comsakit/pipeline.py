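"""End-to-end orchestration on synthetic data.

``run_full`` executes the whole analysis shape — generate a congeneric
series and a receptor-response dataset, compute SOM-surface (CoMSA) and
lattice-field (CoMFA) descriptor matrices, pre-filter, PCA, train/test
partition validation (SMV), IVE-PLS receptor selection, and the residue
selection profile — with every stage writing its outputs as files so any
stage can be rerun in isolation. A manifest records the configuration,
seeds, SHA-256 digests of every output, and stage timings; a rerun with
the same config reproduces the digests byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import adr, chemometrics, fields, som, synth, validation
from .core import (FLOAT_FMT, ensure_outdir, write_activities, write_matrix,
                   write_molecules)

log = logging.getLogger("comsakit")

#: Default configuration; every key can be overridden.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    # synthetic data
    "n_molecules": 20,
    "n_scaffold_atoms": 15,
    "n_substituent_atoms": 5,
    "noise_sd": 0.05,
    # CoMSA
    "som_rows": 20,
    "som_cols": 20,
    "winning_distance": 2.0,
    "points_per_atom": 10,
    "radius_scale": 1.0,
    "epochs": 5,
    # CoMFA
    "spacing": 2.0,
    "margin": 4.0,
    "cutoff": 30.0,
    "sigma": 2.0,
    # modelling
    "max_components": 7,
    "k_test": 6,
    "smv_mode": "sampled",
    "smv_samples": 300,
    "smv_max_components": 3,
    "q2_threshold": 0.75,
    "ive_min_columns": 2,
}


@dataclasses.dataclass
class RunManifest:
    config: dict
    digests: dict[str, str]
    timings: dict[str, float]
    shapes: dict[str, list[int]]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full(config: dict | None = None, out_dir="comsakit_run") -> RunManifest:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    out = ensure_outdir(out_dir)
    seed = int(cfg["seed"])
    digests: dict[str, str] = {}
    timings: dict[str, float] = {}
    shapes: dict[str, list[int]] = {}

    def _finish(stage: str, t0: float, files: list[Path]):
        timings[stage] = round(time.perf_counter() - t0, 3)
        for f in files:
            digests[f.name] = _sha256(f)

    try:
        # --- synth -------------------------------------------------------
        t0 = time.perf_counter()
        spec = synth.SyntheticSpec(
            n_molecules=int(cfg["n_molecules"]),
            n_scaffold_atoms=int(cfg["n_scaffold_atoms"]),
            n_substituent_atoms=int(cfg["n_substituent_atoms"]),
            noise_sd=float(cfg["noise_sd"]), seed=seed)
        molecules = synth.make_molecule_set(spec)
        activities = pd.Series({m.id: m.activity for m in molecules},
                               name="activity")
        truth = synth.ResponseTruth()
        responses, resp_activity = synth.make_response_dataset(
            int(cfg["n_molecules"]), truth, seed=seed)
        f_mol = out / "molecules.csv"
        f_act = out / "activities.csv"
        f_resp = out / "responses.csv"
        f_ract = out / "response_activities.csv"
        f_truth = out / "truth.json"
        write_molecules(molecules, f_mol)
        write_activities(activities, f_act)
        write_matrix(responses, f_resp)
        write_activities(resp_activity, f_ract)
        f_truth.write_text(json.dumps({
            "coefficients": truth.coefficients,
            "noise_sd": truth.noise_sd,
            "clip_range": list(truth.clip_range),
            "decanoic_shift": truth.decanoic_shift,
            "molecule_activity": {
                "intercept": spec.activity_intercept,
                "slope": spec.activity_slope,
            }}, indent=2, sort_keys=True))
        shapes["responses"] = list(responses.shape)
        _finish("synth", t0, [f_mol, f_act, f_resp, f_ract, f_truth])

        # --- CoMSA -------------------------------------------------------
        t0 = time.perf_counter()
        template = min(molecules, key=lambda m: m.activity)  # most active
        X_comsa = som.comsa_matrix(
            template, molecules, rows=int(cfg["som_rows"]),
            cols=int(cfg["som_cols"]),
            winning_distance=float(cfg["winning_distance"]),
            points_per_atom=int(cfg["points_per_atom"]),
            radius_scale=float(cfg["radius_scale"]),
            epochs=int(cfg["epochs"]), seed=seed)
        f_comsa = out / "comsa_matrix.csv"
        write_matrix(X_comsa, f_comsa)
        shapes["comsa_matrix"] = list(X_comsa.shape)
        _finish("comsa", t0, [f_comsa])

        # --- CoMFA -------------------------------------------------------
        t0 = time.perf_counter()
        X_comfa, lattice = fields.comfa_matrix(
            molecules, spacing=float(cfg["spacing"]),
            margin=float(cfg["margin"]), cutoff=float(cfg["cutoff"]))
        f_comfa = out / "comfa_matrix.csv"
        f_lat = out / "lattice.json"
        write_matrix(X_comfa, f_comfa)
        f_lat.write_text(json.dumps({
            "origin": list(lattice.origin), "spacing": lattice.spacing,
            "n_nodes": list(lattice.n_nodes),
            "total_nodes": lattice.total_nodes}, indent=2, sort_keys=True))
        shapes["comfa_matrix"] = list(X_comfa.shape)
        _finish("comfa", t0, [f_comfa, f_lat])

        # --- filtering ---------------------------------------------------
        t0 = time.perf_counter()
        comsa_filt, report = chemometrics.prefilter_columns(X_comsa)
        comfa_filt = fields.variance_filter(X_comfa, sigma=float(cfg["sigma"]))
        f_cf = out / "comsa_filtered.csv"
        f_ff = out / "comfa_filtered.csv"
        f_rep = out / "prefilter_report.csv"
        write_matrix(comsa_filt, f_cf)
        write_matrix(comfa_filt, f_ff)
        report.to_csv(f_rep, index=False)
        shapes["comsa_filtered"] = list(comsa_filt.shape)
        shapes["comfa_filtered"] = list(comfa_filt.shape)
        _finish("filter", t0, [f_cf, f_ff, f_rep])

        # --- PCA ---------------------------------------------------------
        t0 = time.perf_counter()
        pca = chemometrics.pca_decompose(comsa_filt, mode="autoscale")
        f_scores = out / "pca_scores.csv"
        f_expl = out / "pca_explained.csv"
        pd.DataFrame(pca.scores, index=pca.row_ids,
                     columns=[f"PC{i + 1}" for i in range(pca.scores.shape[1])]
                     ).to_csv(f_scores, float_format=FLOAT_FMT)
        pd.Series(pca.explained,
                  index=[f"PC{i + 1}" for i in range(len(pca.explained))],
                  name="explained_fraction").to_csv(f_expl,
                                                    float_format=FLOAT_FMT)
        _finish("pca", t0, [f_scores, f_expl])

        # --- SMV ---------------------------------------------------------
        t0 = time.perf_counter()
        smv = validation.run_smv(
            comsa_filt, activities, k_test=int(cfg["k_test"]),
            max_components=int(cfg["smv_max_components"]),
            mode=str(cfg["smv_mode"]),
            n_samples=int(cfg["smv_samples"]) if cfg["smv_samples"] else None,
            seed=seed)
        freq = validation.test_membership_frequency(
            smv, q2_threshold=float(cfg["q2_threshold"]))
        f_smv = out / "smv_records.csv"
        f_freq = out / "smv_test_frequency.csv"
        smv.records.to_csv(f_smv, index=False, float_format=FLOAT_FMT)
        freq.rename_axis("compound").to_csv(f_freq, float_format=FLOAT_FMT)
        shapes["smv_records"] = list(smv.records.shape)
        _finish("smv", t0, [f_smv, f_freq])

        # --- IVE-PLS on receptor responses -------------------------------
        t0 = time.perf_counter()
        trace = chemometrics.ive_pls(
            responses, resp_activity,
            max_components=int(cfg["max_components"]),
            min_columns=int(cfg["ive_min_columns"]))
        profile = adr.residue_selection_profile(trace.selected_columns)
        f_trace = out / "ive_trace.csv"
        f_sel = out / "ive_selected.csv"
        trace.to_frame().to_csv(f_trace, float_format=FLOAT_FMT)
        pd.Series(trace.selected_columns, name="receptor"
                  ).to_csv(f_sel, index=False)
        profile_files = []
        for key, frame in profile.items():
            f = out / f"profile_{key}.csv"
            frame.rename_axis(key).to_csv(f, float_format=FLOAT_FMT)
            profile_files.append(f)
        shapes["ive_selected"] = [len(trace.selected_columns)]
        _finish("ive", t0, [f_trace, f_sel] + profile_files)
    except Exception as e:
        partial = RunManifest(cfg, digests, timings, shapes)
        (out / "manifest.json").write_text(partial.to_json())
        stage = list(timings)[-1] if timings else "synth"
        raise RuntimeError(f"pipeline aborted after stage {stage!r}: {e}") from e

    manifest = RunManifest(cfg, digests, timings, shapes)
    (out / "manifest.json").write_text(manifest.to_json())
    log.info("pipeline complete: %d output files in %s", len(digests), out)
    return manifest
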
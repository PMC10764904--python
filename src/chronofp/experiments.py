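"""Simulation studies exercising the pipeline end to end.

Three desk-scale experiments on synthetic patients:

* :func:`sop_recovery` — plant a single preictal stage of known duration
  with a strong alpha-band signature and check that the (k, C, SOP) grid
  search recovers the planted SOP;
* :func:`null_calibration` — patients with ``effect_size=0`` carry no
  preictal signal, so the surrogate test should validate (at alpha=0.05)
  only a small fraction of models — a Type-I error check;
* :func:`cascade_detection` — patients with a strong three-stage cascade
  (theta, then alpha, then beta power boosts) should be predicted by the
  Cumulative strategy with high sensitivity and statistical validation,
  while shuffling the stage order in the test data breaks the Chronological
  strategy's ordered-event detection.

Problem sizes (4 channels, gaps of tens of minutes, 10 replicate patients)
are the package's desk-scale study conditions; all durations flow from the
configs below, never from constants in pipeline code.
"""

from __future__ import annotations

import numpy as np

from . import evaluation, postproc
from .dataset import EventScheme, label_windows, split_train_test
from .features import FeatureTable, extract_features
from .model import GridSpec, grid_search, predict_vote, train_ensemble
from .pipeline import RunConfig, derive_seed, run_approach
from .synthetic import StageSpec, SyntheticConfig, generate_patient


def _patient_seed(seed: int, tag: str, i: int) -> int:
    return derive_seed(seed, "experiment", tag, i)


# ---------------------------------------------------------------------------
# SOP recovery
# ---------------------------------------------------------------------------

RECOVERY_STAGE_MIN = 20.0
RECOVERY_GRID = GridSpec(k_grid=(10, 20), c_grid=(0.25, 1.0, 4.0),
                         sop_grid=(10, 15, 20, 25, 30))


def recovery_config(seed: int) -> SyntheticConfig:
    return SyntheticConfig(
        n_channels=4,
        n_seizures=4,
        interictal_gap_min=80.0,
        preictal_stages=[StageSpec(1, RECOVERY_STAGE_MIN, {"alpha": 4.0})],
        effect_size=1.0,
        seed=seed,
    )


def sop_recovery(n_runs: int = 10, seed: int = 1) -> dict:
    """Fraction of seeded runs whose grid search selects the planted SOP."""
    selected = []
    for i in range(n_runs):
        cfg = recovery_config(_patient_seed(seed, "recovery", i))
        rec = generate_patient(cfg)
        table = extract_features(rec)
        train_onsets, _ = split_train_test(rec.onsets)
        cut = train_onsets[-1] + 10.0 * 60.0
        mask = table.window_times < cut
        train_table = FeatureTable(table.values[mask], table.window_times[mask],
                                   table.manifest)
        gs = grid_search(train_table, train_onsets, RECOVERY_GRID, "control",
                         seed=_patient_seed(seed, "recovery-grid", i))
        selected.append(gs.sop)
    hits = sum(1 for s in selected if s == RECOVERY_STAGE_MIN)
    return {"selected_sops": selected, "n_runs": n_runs,
            "recovery_rate": hits / n_runs}


# ---------------------------------------------------------------------------
# surrogate Type-I calibration on null patients
# ---------------------------------------------------------------------------

def null_config(seed: int) -> SyntheticConfig:
    return SyntheticConfig(
        n_channels=3,
        n_seizures=4,
        interictal_gap_min=40.0,
        effect_size=0.0,
        seed=seed,
    )


def null_calibration(n_patients: int = 50, seed: int = 1) -> dict:
    """Fraction of null-patient models the surrogate test validates."""
    validated = []
    grid = GridSpec(k_grid=(10,), c_grid=(1.0,), sop_grid=(10,))
    for i in range(n_patients):
        cfg = RunConfig(
            synthetic=null_config(_patient_seed(seed, "null", i)),
            approaches=("control",),
            grid=grid,
            seed=_patient_seed(seed, "null-run", i),
        )
        rec = generate_patient(cfg.synthetic)
        table = extract_features(rec)
        res = run_approach(table, rec.onsets, "control", cfg, rec.duration_s,
                           fixed_params=(10, 1.0, 10))
        validated.append(bool(res["validated"]))
    frac = float(np.mean(validated))
    return {"validated": validated, "n_patients": n_patients,
            "validated_fraction": frac}


# ---------------------------------------------------------------------------
# planted-cascade detection
# ---------------------------------------------------------------------------

CASCADE_SOP = 10
CASCADE_DELTAS = ({"theta": 4.0}, {"alpha": 4.0}, {"beta": 4.0})


def cascade_config(seed: int, order: tuple[int, int, int] = (0, 1, 2)) -> SyntheticConfig:
    """Three 10-min stages; ``order`` permutes which signature lands where."""
    return SyntheticConfig(
        n_channels=4,
        n_seizures=5,
        interictal_gap_min=80.0,
        preictal_stages=[
            StageSpec(k + 1, float(CASCADE_SOP), CASCADE_DELTAS[order[k]])
            for k in range(3)
        ],
        effect_size=1.0,
        seed=seed,
    )


def _cascade_curves(bundles, scheme, table, test_mask):
    X = table.values[test_mask]
    t = table.window_times[test_mask]
    curves = []
    for ev, bundle in enumerate(bundles, start=1):
        O = predict_vote(bundle, X)
        curves.append(postproc.firing_power(O, postproc.event_tau(scheme, ev),
                                            times=t))
    return curves


def cascade_detection(n_runs: int = 10, seed: int = 1,
                      k: int = 20, C: float = 1.0) -> dict:
    """Cumulative vs Chronological detection of a planted ordered cascade.

    For each replicate: train Cumulative and Chronological ensembles on the
    ordered patient, evaluate both on its test stretch, then evaluate the
    Chronological model again on a patient whose stage signatures are
    shuffled (beta, theta, alpha instead of theta, alpha, beta).
    """
    sph, excl = 5.0, 10.0
    shuffled_order = (2, 0, 1)
    out = {"cumulative_ss": [], "cumulative_validated": [],
           "chronological_ss": [], "chronological_ss_shuffled": []}
    for i in range(n_runs):
        run_seed = _patient_seed(seed, "cascade", i)
        rec = generate_patient(cascade_config(run_seed))
        table = extract_features(rec)
        train_onsets, test_onsets = split_train_test(rec.onsets)
        cut = float(train_onsets[-1] + excl * 60.0)
        train_mask = table.window_times < cut
        train_table = FeatureTable(table.values[train_mask],
                                   table.window_times[train_mask],
                                   table.manifest)

        schemes = {a: EventScheme(a, CASCADE_SOP, sph)
                   for a in ("cumulative", "chronological")}
        bundles = {}
        for a, scheme in schemes.items():
            bundles[a] = [
                train_ensemble(
                    label_windows(train_table, train_onsets, scheme, ev, excl),
                    k, C, seed=derive_seed(run_seed, "ens", a, ev),
                    approach=a, event_index=ev, sop=CASCADE_SOP)
                for ev in range(1, 4)
            ]

        refractory = CASCADE_SOP + sph
        span = 3.0 * CASCADE_SOP
        test_mask = ~train_mask

        # Cumulative on the ordered patient
        scheme = schemes["cumulative"]
        curves = _cascade_curves(bundles["cumulative"], scheme, table, test_mask)
        alarms = postproc.alarms_cumulative(curves, span_limit_min=span,
                                            refractory_min=refractory)
        inter_h = evaluation.interictal_hours(cut, rec.duration_s, test_onsets,
                                              scheme.total_span_min, excl)
        res = evaluation.score_alarms(alarms, test_onsets, CASCADE_SOP, sph,
                                      inter_h)
        surr = evaluation.surrogate_test(
            alarms, test_onsets, cut, rec.duration_s, CASCADE_SOP, sph,
            preictal_span_min=scheme.total_span_min, exclusion_min=excl,
            seed=derive_seed(run_seed, "surr", "cumulative"))
        out["cumulative_ss"].append(res.ss)
        out["cumulative_validated"].append(bool(surr.validated))

        # Chronological on the ordered patient
        scheme = schemes["chronological"]
        curves = _cascade_curves(bundles["chronological"], scheme, table,
                                 test_mask)
        alarms = postproc.alarms_chronological(curves, span_limit_min=span,
                                               refractory_min=refractory)
        res = evaluation.score_alarms(alarms, test_onsets, CASCADE_SOP, sph,
                                      inter_h)
        out["chronological_ss"].append(res.ss)

        # Chronological model applied to a shuffled-order test recording
        rec_sh = generate_patient(cascade_config(
            _patient_seed(seed, "cascade-shuffled", i), shuffled_order))
        test_rec = rec_sh.slice_time(cut)
        table_sh = extract_features(test_rec)
        t_sh = table_sh.window_times + cut
        sh_onsets = test_rec.onsets + cut
        curves = []
        for ev, bundle in enumerate(bundles["chronological"], start=1):
            O = predict_vote(bundle, table_sh.values)
            curves.append(postproc.firing_power(
                O, postproc.event_tau(scheme, ev), times=t_sh))
        alarms = postproc.alarms_chronological(curves, span_limit_min=span,
                                               refractory_min=refractory)
        res = evaluation.score_alarms(alarms, sh_onsets, CASCADE_SOP, sph,
                                      inter_h)
        out["chronological_ss_shuffled"].append(res.ss)

    out["n_runs"] = n_runs
    out["cumulative_ss_mean"] = float(np.mean(out["cumulative_ss"]))
    out["cumulative_detection_rate"] = float(np.mean(
        [ss >= 0.8 and v for ss, v in
         zip(out["cumulative_ss"], out["cumulative_validated"])]))
    out["chronological_ss_mean"] = float(np.mean(out["chronological_ss"]))
    out["chronological_ss_shuffled_mean"] = float(
        np.mean(out["chronological_ss_shuffled"]))
    return out
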
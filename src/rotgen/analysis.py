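"""Derived statistics and the end-to-end cohort pipeline.

The headline per-participant index is *2Dness*: the difference in maximised
log-likelihood between the rotation-invariant ``2D`` model and the best
single-dimension model on the near-transfer fit. Positive values indicate
rotational generalisation. Cohort-level reporting mirrors the group
analyses: Dirichlet random-effects model frequencies, family collapses
(1D-family vs 2D, random vs the rest) and pairwise between-group Bayes
factors with Jeffreys-style labels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .bms import between_group_bf, evidence_from_bic, family_collapse, rfx_bms
from .fitting import SelectionResult, fits_to_frame, select_best
from .models import model_roster
from .simulate import AgentSpec, simulate_mapping_agent, simulate_participant
from .task import build_schedule

logger = logging.getLogger("rotgen")

#: family partitions mirroring the published group comparisons
FAMILY_PARTITIONS = {
    "near": {
        "1D_vs_2D": {"1D": ["1Di_u", "1Dj_u", "1Di_s", "1Dj_s"], "2D": ["2D"]},
        "R_vs_rest": {"random": ["R", "Rp"],
                      "informed": ["1Di_u", "1Dj_u", "1Di_s", "1Dj_s", "2D"]},
    },
    "far": {
        "1D_vs_2D": {"1D": ["1Di_u", "1Dij_u", "1Dj_u", "1Dji_u",
                            "1Di_s", "1Dij_s", "1Dj_s", "1Dji_s"],
                     "2D": ["2D"]},
        "R_vs_rest": {"random": ["R", "Rp"],
                      "informed": ["1Di_u", "1Dij_u", "1Dj_u", "1Dji_u",
                                   "1Di_s", "1Dij_s", "1Dj_s", "1Dji_s", "2D"]},
    },
}


@dataclass
class CorrelationReport:
    """Pearson (optionally partial) correlation with a two-sided p-value."""

    label: str
    r: float
    p_value: float
    n: int
    partial_controls: tuple[str, ...] = ()


def two_d_ness(selection: SelectionResult) -> float:
    """ln L(2D) - max over 1D models of ln L(1D); positive = 2D behaviour."""
    one_d = [f.max_log_likelihood for f in selection.fits.values()
             if f.model not in ("R", "Rp", "2D")]
    if "2D" not in selection.fits or not one_d:
        raise ValueError("need fits for the 2D model and at least one 1D model")
    return selection.fits["2D"].max_log_likelihood - max(one_d)


def normalised_log_likelihood(selection: SelectionResult, model: str) -> float:
    """ln L(model) - ln L(R): likelihood relative to the random baseline."""
    return (selection.fits[model].max_log_likelihood
            - selection.fits["R"].max_log_likelihood)


def pearson(x, y, label: str = "r") -> CorrelationReport:
    """Standard Pearson r with the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return CorrelationReport(label, float(r), float(p), len(x))


def _residualise(v: np.ndarray, controls: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(v)), controls])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def partial_correlation(x, y, controls, label: str = "partial_r",
                        control_names=()) -> CorrelationReport:
    """Partial Pearson correlation via double residualisation on controls."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    controls = np.atleast_2d(np.asarray(controls, dtype=float))
    if controls.shape[0] != len(x):
        controls = controls.T
    n, k = controls.shape
    if len(x) != len(y) or len(x) != n or n < k + 3:
        raise ValueError("need equal-length inputs with n >= n_controls + 3")
    rx = _residualise(x, controls)
    ry = _residualise(y, controls)
    if (np.std(rx) <= 1e-10 * max(1.0, np.std(x))
            or np.std(ry) <= 1e-10 * max(1.0, np.std(y))):
        raise ValueError("zero residual variance (degenerate controls)")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    t = r * np.sqrt(df / max(1e-300, 1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationReport(label, r, p, n, tuple(control_names))


# ---------------------------------------------------------------------------
# cohort pipeline
# ---------------------------------------------------------------------------

def _mean_accuracy(dataset, phases) -> float:
    idx = [k for k, t in enumerate(dataset.trials) if t.phase in phases]
    if not idx:
        return float("nan")
    hits = [dataset.choices[k] == dataset.trials[k].category for k in idx]
    return float(np.mean(hits))


def analyse_participant(dataset, selection: SelectionResult,
                        mapping_accuracy: float = float("nan")) -> dict:
    """One participant's derived statistics (2Dness, accuracies, best model)."""
    return {
        "participant_id": dataset.participant_id,
        "two_d_ness": two_d_ness(selection),
        "pretraining_accuracy": _mean_accuracy(dataset, ("pretraining",)),
        "training_accuracy": _mean_accuracy(dataset, ("training",)),
        "mapping_accuracy": mapping_accuracy,
        "best_model": selection.best_model,
    }


def _evidence_matrix(selections, roster) -> np.ndarray:
    return np.array([[evidence_from_bic(sel.fits[m.name].bic) for m in roster]
                     for sel in selections])


def _restrict_to_partition(selections, log_ev, roster, partition):
    """Keep participants whose BIC-best model lies inside the partition."""
    member_names = {roster[i].name for idx in partition.values() for i in idx}
    keep = [k for k, sel in enumerate(selections)
            if sel.best_model in member_names]
    return log_ev[keep] if keep else log_ev[:0]


def cohort_bms(selections, transfer_kind: str, alpha0: float = 1.0) -> dict:
    """Model frequencies and family frequencies for one cohort."""
    roster = model_roster(transfer_kind)
    log_ev = _evidence_matrix(selections, roster)
    full = rfx_bms(log_ev, alpha0)
    out = {
        "n_participants": len(selections),
        "model_frequencies": {m.name: float(f)
                              for m, f in zip(roster, full.frequencies)},
        "best_model_counts": pd.Series(
            [s.best_model for s in selections]).value_counts().to_dict(),
        "families": {},
    }
    names = [m.name for m in roster]
    for pname, fam in FAMILY_PARTITIONS[transfer_kind].items():
        idx_partition = {f: [names.index(n) for n in members]
                         for f, members in fam.items()}
        sub = _restrict_to_partition(selections, log_ev, roster, idx_partition)
        if len(sub) == 0:
            out["families"][pname] = {"n_participants": 0}
            continue
        collapsed = family_collapse(sub, idx_partition)
        res = rfx_bms(collapsed, alpha0)
        out["families"][pname] = {
            "n_participants": int(len(sub)),
            "frequencies": {f: float(v) for f, v in
                            zip(idx_partition, res.frequencies)},
        }
    return out


def pairwise_bf(selections_a, selections_b, transfer_kind: str,
                alpha0: float = 1.0) -> dict:
    """Family-wise between-group BFs for a pair of cohorts."""
    roster = model_roster(transfer_kind)
    names = [m.name for m in roster]
    ev_a = _evidence_matrix(selections_a, roster)
    ev_b = _evidence_matrix(selections_b, roster)
    out = {}
    for pname, fam in FAMILY_PARTITIONS[transfer_kind].items():
        idx_partition = {f: [names.index(n) for n in members]
                         for f, members in fam.items()}
        sub_a = _restrict_to_partition(selections_a, ev_a, roster, idx_partition)
        sub_b = _restrict_to_partition(selections_b, ev_b, roster, idx_partition)
        if len(sub_a) == 0 or len(sub_b) == 0:
            out[pname] = {"bf": float("nan"), "label": "undefined",
                          "n_a": int(len(sub_a)), "n_b": int(len(sub_b))}
            continue
        res = between_group_bf(family_collapse(sub_a, idx_partition),
                               family_collapse(sub_b, idx_partition), alpha0)
        out[pname] = {
            "bf": res.bf, "log_bf": res.log_bf, "p_h0": res.p_h0,
            "label": res.label, "n_a": int(len(sub_a)), "n_b": int(len(sub_b)),
        }
    return out


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Simulate cohorts, fit, select, and report — a pure function of config.

    ``config`` keys: ``seed`` (master seed), ``transfer`` ("near"/"far"),
    ``cohorts`` (list of {name, experiment_id, model, beta, n,
    mapping_agent?}), optional ``pairs`` (cohort-name pairs for the
    between-group BFs). Writes ``fits.csv``, ``analysis.csv`` and
    ``bms.json`` when ``out_dir`` is given, and returns the report dict.
    """
    seed = int(config.get("seed", 0))
    transfer = config.get("transfer", "near")
    cohorts = config["cohorts"]
    master = np.random.SeedSequence(seed)
    streams = master.spawn(len(cohorts))
    report = {"seed": seed, "transfer": transfer, "cohorts": {}, "pairs": {}}
    all_selections: dict[str, list[SelectionResult]] = {}
    fit_frames = []
    analysis_rows = []
    for cohort, stream in zip(cohorts, streams):
        name = cohort["name"]
        logger.info("simulating cohort %s (%s x %d agents of %s)",
                    name, cohort["experiment_id"], cohort["n"], cohort["model"])
        child = [int(s.generate_state(1)[0] % (2**31))
                 for s in stream.spawn(3 * cohort["n"])]
        selections = []
        for k in range(cohort["n"]):
            schedule = build_schedule(cohort["experiment_id"], child[3 * k])
            ds = simulate_participant(
                AgentSpec(cohort["model"], cohort["beta"], child[3 * k + 1]),
                schedule, participant_id=f"{name}_{k:03d}")
            mapping_trials = [t for ph in schedule.phases
                              if ph.task == "mapping" for t in ph.trials]
            map_acc = float("nan")
            if mapping_trials:
                map_acc = simulate_mapping_agent(
                    cohort.get("mapping_agent", "perfect"),
                    mapping_trials, child[3 * k + 2])
            sel = select_best(ds, transfer)
            selections.append(sel)
            analysis_rows.append({"cohort": name,
                                  **analyse_participant(ds, sel, map_acc)})
        all_selections[name] = selections
        frame = fits_to_frame(selections)
        frame.insert(0, "cohort", name)
        fit_frames.append(frame)
        report["cohorts"][name] = cohort_bms(selections, transfer)
    for pair in config.get("pairs", []):
        a, b = pair
        report["pairs"][f"{a}|{b}"] = pairwise_bf(
            all_selections[a], all_selections[b], transfer)
    fits = pd.concat(fit_frames, ignore_index=True)
    analysis = pd.DataFrame(analysis_rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fits.to_csv(out / "fits.csv", index=False)
        analysis.to_csv(out / "analysis.csv", index=False)
        with open(out / "bms.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        logger.info("wrote fits.csv, analysis.csv, bms.json to %s", out)
    return {"report": report, "fits": fits, "analysis": analysis}
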
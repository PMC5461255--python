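"""End-to-end orchestration: generate -> derive -> analyze -> report.

Ties the synthetic generator, predictor derivation and the
selection-inside-LOOCV analysis together and emits a reproducible JSON
report (schema version, seeds and all thresholds recorded) plus CSV tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, selection, synthetic
from .battery import CANONICAL_PREDICTORS, BatteryDataset
from .scoring import group_summary, learning_curve

__all__ = ["RunConfig", "run_synthetic_end_to_end", "validate_dataset",
           "analyze_dataset"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Settings of one pipeline run; round-trips through JSON."""

    out_dir: str = "vocopred_run"
    seed: int = 0
    n_perm: int = 1000
    sweep_start: int = 2
    sweep_stop: int | None = None  # inclusive; default: all 13 variables
    n_selected: int = 6
    n_components: int = 2
    scale: bool = True
    recall_sign: str = "t7_minus_t5"
    exclude_zero_scores: bool = False
    missing_ospan_old: int = 0
    generator: dict | None = None  # overrides for the bundled calibration
    make_plots: bool = False

    def generator_config(self) -> synthetic.GeneratorConfig:
        overrides = dict(self.generator or {})
        overrides.setdefault("missing_ospan_old", self.missing_ospan_old)
        return synthetic.default_config(**overrides)


def validate_dataset(path) -> BatteryDataset:
    """Load and validate a battery CSV (canonical header, value ranges,
    missing-data policy).  Subjects with missing predictors stay in the
    table but are excluded from the analysis view; the exclusion is logged
    in the returned dataset via :meth:`BatteryDataset.excluded_subjects`."""
    ds = BatteryDataset.from_csv(path)
    y = ds.frame["y_median"].dropna()
    if ((y < 0) | (y > 7)).any():
        raise ValueError("response values outside the 0-7 words-per-sentence range")
    return ds


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def analyze_dataset(dataset: BatteryDataset, cfg: RunConfig) -> dict:
    """Run the full inference chain on a validated dataset.

    Sweep over candidate variable counts, subgroup significance, final
    selection-free evaluation of the top variable set, univariate
    correlations, and (optionally) the zero-score robustness rerun.
    """
    X, y, groups = dataset.analysis_view()
    p = X.shape[1]
    stop = cfg.sweep_stop or p
    js = range(cfg.sweep_start, stop + 1)
    ss = np.random.SeedSequence(cfg.seed)
    s_sweep, s_final, s_uni, s_zero = ss.spawn(4)

    sweep = selection.sweep_variable_counts(
        X, y, js, n_components=cfg.n_components, scale=cfg.scale,
        n_perm=cfg.n_perm, seed=s_sweep, groups=groups,
    )
    order = selection.rank_by_vip(X, y, n_components=cfg.n_components,
                                  scale=cfg.scale)
    selected = [CANONICAL_PREDICTORS[i] for i in order[: cfg.n_selected]]
    final = selection.evaluate_final(
        X, y, selected, n_components=cfg.n_components, scale=cfg.scale,
        n_perm=cfg.n_perm, seed=s_final,
    )
    uni = selection.univariate_correlations(
        X, y, selected, n_perm=cfg.n_perm, seed=s_uni
    )
    summary = group_summary(y, groups)

    result = {
        "n_subjects_analyzed": int(len(y)),
        "excluded_subjects": dataset.excluded_subjects(),
        "group_summary": summary,
        "sweep": sweep.drop(columns=[]).to_dict(orient="records"),
        "selected_variables": selected,
        "final_evaluation": {
            "variables": final.variables,
            "r": _jsonable(final.r),
            "p": _jsonable(final.p),
            "rmsep": _jsonable(final.rmsep),
        },
        "subgroup_pvalues": _jsonable(
            {
                int(j): res.group_pvalues
                for j, res in sweep.attrs["results"].items()
                if res.group_pvalues is not None
            }
        ),
        "univariate_correlations": uni.to_dict(orient="records"),
    }
    if cfg.exclude_zero_scores:
        zero = selection.rerun_excluding_zero_scores(
            X, y, groups=groups, j_range=js, n_selected=cfg.n_selected,
            n_components=cfg.n_components, scale=cfg.scale,
            n_perm=cfg.n_perm, seed=s_zero,
        )
        result["zero_score_rerun"] = {
            "n_removed": zero["n_removed"],
            "selected_primary": zero["primary"]["selected"],
            "selected_excluding_zero": zero["excluding_zero"]["selected"],
            "selection_overlap": zero["selection_overlap"],
            "final_excluding_zero": {
                "r": _jsonable(zero["excluding_zero"]["final"].r),
                "rmsep": _jsonable(zero["excluding_zero"]["final"].rmsep),
            },
        }
    return _jsonable(result)


def _plot_sweep(sweep_records: list[dict], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pd.DataFrame(sweep_records)
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    for col, a in zip(axes.T, (1, 2)):
        sub = df[df["component"] == a]
        col[0].plot(sub["j"], sub["p_value"], "o-")
        col[0].axhline(0.05, ls=":", color="k")
        col[0].set_title(f"component {a}")
        col[0].set_ylabel("permutation p")
        col[1].plot(sub["j"], sub["msep"], "o-")
        col[1].plot(sub["j"], sub["msep_null"], "s--", label="null model")
        col[1].set_ylabel("MSEP")
        col[1].set_xlabel("variables included (j)")
        col[1].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_synthetic_end_to_end(cfg: RunConfig) -> dict:
    """Synthetic demo of the whole pipeline.

    Generates a battery plus trial records, re-derives the 13 predictors
    from the raw records, verifies the round trip, runs the analysis and
    writes ``report.json``, the battery/trial/raw CSVs and the learning
    curve to ``cfg.out_dir``.  Fixed seed -> byte-identical report.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen_cfg = cfg.generator_config()
    battery, trials, raw = synthetic.generate_trial_records(gen_cfg, seed=cfg.seed)

    from .derive import derive_predictors_frame

    derived = derive_predictors_frame(raw, recall_sign=cfg.recall_sign)
    ok = battery.frame.apply(synthetic.representable, axis=1).to_numpy()
    gap = np.abs(
        derived[list(CANONICAL_PREDICTORS)].to_numpy(float)
        - battery.frame[list(CANONICAL_PREDICTORS)].to_numpy(float)
    )
    roundtrip_err = float(np.nanmax(gap[ok])) if ok.any() else float("nan")
    n_saturated = int(np.count_nonzero(~ok))

    analysis = analyze_dataset(battery, cfg)
    trials_g = trials.merge(
        battery.frame[["subject_id", "age_group"]], on="subject_id"
    )
    curve = learning_curve(trials_g)

    truth = synthetic.signal_variables(gen_cfg)
    recovered = sorted(set(analysis["selected_variables"]) & set(truth))
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "config": asdict(cfg),
        "seed": cfg.seed,
        "derivation_roundtrip_max_abs_error": roundtrip_err,
        "n_subjects_outside_test_ranges": n_saturated,
        "generator_signal_variables": truth,
        "recovered_signal_variables": recovered,
        "analysis": analysis,
        "learning_curve": _jsonable(
            {str(c): curve[c].tolist() for c in curve.columns}
        ),
    }

    battery.to_csv(out / "battery.csv")
    trials.to_csv(out / "trials.csv", index=False)
    raw.to_csv(out / "raw_records.csv", index=False)
    pd.DataFrame(analysis["sweep"]).to_csv(out / "sweep.csv", index=False)
    text = json.dumps(report, indent=2, sort_keys=True)
    (out / "report.json").write_text(text + "\n")
    if cfg.make_plots:
        _plot_sweep(analysis["sweep"], out / "sweep.png")
    return report
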
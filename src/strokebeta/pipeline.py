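"""End-to-end orchestration: simulate -> features -> contrasts -> predict.

One run = one output directory containing the resolved configuration, the
cohort table, tidy contrast results, the prediction report, a markdown
summary, and a manifest with content hashes so reruns under the same seed
can be verified bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (build_cohort_table, run_function_contrast,
                     run_recovery_contrast)
from .prediction import loocv_evaluate, standardize, vif_screen, \
    forward_stepwise
from .synthetic import CohortConfig, generate_cohort

__all__ = ["RunConfig", "run_all", "report", "CANDIDATE_FEATURES"]

#: the seven candidate predictors of recovery: ipsilesional M1 and S1
#: rebound power, intra- and inter-hemispheric S1-M1 coupling strength,
#: lesion volume, and mean projection / commissural tract disconnection
CANDIDATE_FEATURES = (
    "psd_cM1", "psd_cS1", "msc_cM1_cS1", "msc_cM1_iS1",
    "lesion_volume", "projection_mean", "commissural_mean",
)


@dataclass
class RunConfig:
    out_dir: str = "strokebeta_run"
    seed: int = 0
    n_subjects: int = 36
    isi_s: float = 1.5
    n_stimuli: int = 60
    effect_sizes: dict = field(default_factory=dict)
    band: tuple = (13.0, 30.0)
    rebound_window: tuple | None = None     # None -> derive from the data
    n_perm: int = 5000
    n_surrogates: int = 20
    cutoff_s: float = 100.0
    vif_threshold: float = 2.5
    alpha_enter: float = 0.15
    alpha_remove: float = 0.15
    prob_threshold: float = 0.5
    correction: str = "per_test"
    candidates: tuple = CANDIDATE_FEATURES
    write_raw: bool = False

    def __post_init__(self):
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if not 0 < self.cutoff_s:
            raise ValueError("cutoff_s must be positive")
        if self.correction not in ("per_test", "max_stat"):
            raise ValueError("correction must be per_test or max_stat")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, default=str) + "\n")


def run_all(config: RunConfig) -> Path:
    """Execute every stage and return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(4)

    # stage 1: simulate
    cohort_cfg = CohortConfig(
        n_subjects=config.n_subjects, isi_s=config.isi_s,
        n_stimuli=config.n_stimuli,
        group_effect_sizes=dict(config.effect_sizes),
        seed=int(seeds[0]))
    records, truth = generate_cohort(cohort_cfg)
    if config.write_raw:
        from .synthetic import save_cohort

        save_cohort(records, truth, out / "raw")

    # stage 2: preprocessing + feature extraction
    table, window = build_cohort_table(
        records, truth.atlas, truth.streamlines, band=config.band,
        window=config.rebound_window, cutoff_s=config.cutoff_s,
        n_surrogates=config.n_surrogates, seed=int(seeds[1]))
    table.to_csv(out / "cohort_features.csv", index=False)

    # stage 3: contrasts
    func = run_function_contrast(table, n_perm=config.n_perm,
                                 seed=int(seeds[2]),
                                 correction=config.correction)
    func.to_csv(out / "function_contrast.csv", index=False)
    reco = run_recovery_contrast(table, n_perm=config.n_perm,
                                 seed=int(seeds[3]),
                                 correction=config.correction)
    reco.to_csv(out / "recovery_contrast.csv", index=False)

    # stage 4: prediction within the low-function group
    low = table[table["function_group"] == "low"].reset_index(drop=True)
    y = (low["improvement_group"] == "not_improved").astype(int).to_numpy()
    candidates = [c for c in config.candidates
                  if low[c].std(ddof=1) > 0]
    X = low[candidates]
    perf = loocv_evaluate(X, y, threshold=config.prob_threshold,
                          vif_threshold=config.vif_threshold,
                          alpha_enter=config.alpha_enter,
                          alpha_remove=config.alpha_remove)
    Xz, _, _ = standardize(X)
    Xs, merged = vif_screen(Xz, config.vif_threshold)
    full = forward_stepwise(Xs, y, config.alpha_enter,
                            config.alpha_remove)
    pred_report = {
        "outcome_coding": {"improved": 0, "not_improved": 1},
        "rebound_window": list(window),
        "loocv": {
            "brier": perf.brier, "auc": perf.auc,
            "confusion": {"tp": perf.tp, "fp": perf.fp,
                          "tn": perf.tn, "fn": perf.fn},
            "metrics": perf.metrics,
            "metrics_flipped_positive_class": perf.metrics_flipped,
        },
        "full_sample_model": {
            "selected": full.features,
            "coefficients": full.coefficients.tolist(),
            "intercept": full.intercept,
            "wald_p": full.wald_p.tolist(),
            "merged_groups": merged,
        },
    }
    _write_json(pred_report, out / "prediction_report.json")
    pd.DataFrame({"subject_id": low["subject_id"],
                  "y": y, "prob": perf.probabilities}).to_csv(
        out / "loocv_probabilities.csv", index=False)

    _write_json(asdict(config), out / "config_resolved.json")

    # manifest with content hashes of the computed artifacts (the resolved
    # config embeds the output path, so it is recorded but not hashed)
    manifest = {p.name: _sha256(p)
                for p in sorted(out.glob("*.csv"))}
    manifest.update({p.name: _sha256(p)
                     for p in sorted(out.glob("*.json"))
                     if p.name not in ("manifest.json",
                                       "config_resolved.json")})
    _write_json(manifest, out / "manifest.json")
    report(out)
    return out


def _sig_rows(df: pd.DataFrame, analysis_prefix: str) -> pd.DataFrame:
    sub = df[df["analysis"].str.startswith(analysis_prefix)]
    return sub[sub["sig_level"].notna()]


def report(run_dir) -> str:
    """Human-readable markdown summary of a (possibly partial) run."""
    out = Path(run_dir)
    lines = ["# strokebeta run summary", ""]
    done = False

    feats = out / "cohort_features.csv"
    if feats.exists():
        done = True
        table = pd.read_csv(feats)
        n_low = int((table["function_group"] == "low").sum())
        n_high = len(table) - n_low
        low = table[table["function_group"] == "low"]
        n_imp = int((low["improvement_group"] == "improved").sum())
        lines += [
            "## Cohort",
            f"- {len(table)} subjects: {n_low} low / {n_high} high "
            "initial function (NHPT 100 s cutoff)",
            f"- of the low-function group, {n_imp} improved / "
            f"{n_low - n_imp} didn't improve (NHPT T1 - T0 < 0)", "",
        ]

    for fname, title in (("function_contrast.csv",
                          "Initial function (low vs high)"),
                         ("recovery_contrast.csv",
                          "Recovery (improved vs not, low-function only)")):
        p = out / fname
        if not p.exists():
            continue
        done = True
        df = pd.read_csv(p)
        lines += [f"## {title}", ""]
        sig = df[df["sig_level"].notna()]
        if sig.empty:
            lines.append("No significant effects at the 95th percentile.")
        else:
            lines.append("| analysis | feature | t | df | p | level |")
            lines.append("|---|---|---|---|---|---|")
            for _, r in sig.iterrows():
                lines.append(
                    f"| {r['analysis']} ({r['contrast']}) | {r['name']} | "
                    f"{r['t']:.2f} | {int(r['df'])} | {r['p']:.4f} | "
                    f"{r['sig_level']} |")
        lines.append("")

    pred = out / "prediction_report.json"
    if pred.exists():
        done = True
        rep = json.loads(pred.read_text())
        loo = rep["loocv"]
        lines += ["## Recovery prediction (LOOCV)", ""]
        lines.append(f"- selected (full sample): "
                     f"{rep['full_sample_model']['selected']}")
        lines.append(f"- Brier {loo['brier']:.3f}, AUC {loo['auc']:.3f}")
        for name, (est, lo, hi) in loo["metrics"].items():
            lines.append(f"- {name}: {est:.2f} (95% CI {lo:.2f}-{hi:.2f})")
        lines.append("")

    if not done:
        lines.append("no stages completed")
    text = "\n".join(lines) + "\n"
    (out / "report.md").write_text(text)
    return text
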
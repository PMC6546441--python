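"""End-to-end orchestration: calibrate -> score -> analyze.

The pipeline reproduces the study's analysis structure on synthetic data
(or on user-supplied images/annotations/cohort tables): scanner
calibration from gray standards, transect colorimetry of every wing,
then the three analyses — preference GLMM, activity GLMM, pigmentation
linear models — each with BIC backward elimination, likelihood-ratio
(and optionally parametric-bootstrap) p-values, Tukey-adjusted post-hoc
contrasts, and per-cell 1:1 preference tests.

Every run writes a manifest (config hash, derived seeds, library
versions) so any output is traceable, and identical config + seed
reproduce all numeric outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import (
    FULL_FIXED,
    backward_select_bic,
    build_activity_response,
    build_preference_response,
    fit_glmm,
    lmm_term_ftests,
    lrt,
    parametric_bootstrap_p,
    posthoc_pairwise,
    test_vs_even,
)
from .calibration import apply_calibration, fit_calibration
from .colorspace import hsb_to_rgb, rgb_to_xyY
from .model import MixedModelSpec
from .simulate import (
    CohortSimParams,
    WingSimParams,
    derive_seeds,
    generate_calibration_standards,
    generate_cohort_series,
    generate_wing_image,
)
from .transect import crypsis_score, internal_contrast, sample_transect

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full_pipeline", "score_wings", "analyze_behavior", "make_figures"]

BROWN_HSB = (25.0, 0.60, 0.50)
GREEN_HSB = (130.0, 0.60, 0.50)


@dataclass
class PipelineConfig:
    out_dir: str = "wingcrypsis_run"
    seed: int = 1
    n_wings_per_cell: int = 16  # per Td x Ta x sex cell
    n_cohorts_per_cell: int = 8  # per Td x Ta x sex cell
    nsim: int = 0  # parametric-bootstrap draws (0 = LRT only)
    scanner_gamma: float = 2.2  # emulated raw response of the demo scanner
    calibration_degree: int = 3
    pixel_noise_sd: float = 0.01
    brown_hsb: tuple = BROWN_HSB
    green_hsb: tuple = GREEN_HSB
    sigma_cohort: float = 0.5
    sigma_timepoint: float = 0.2
    preference_effects: dict = field(
        default_factory=lambda: {"intercept": -0.3, "Td[19]": 0.8, "Sex[F]": 0.6, "Ta[19]:Sex[F]": 0.4}
    )
    activity_effects: dict = field(
        default_factory=lambda: {"Td[19]": 0.4, "Ta[19]": 0.5, "Td[19]:Sex[F]": -0.4, "Ta[19]:Sex[F]": -0.5}
    )
    force: bool = False

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        cfg = cls(**payload)
        if cfg.nsim < 0:
            raise ValueError("nsim must be >= 0")
        for hsb in (cfg.brown_hsb, cfg.green_hsb):
            hsb_to_rgb(*hsb)  # validates ranges
        return cfg


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=list).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def score_wings(config: PipelineConfig, seed: int, curve) -> pd.DataFrame:
    """Generate, scan-emulate, linearize and score all synthetic wings.

    Returns one tidy row per individual with per-element contrasts and
    crypsis scores against the brown and green assay patches.
    """
    brown = rgb_to_xyY(hsb_to_rgb(*config.brown_hsb))
    green = rgb_to_xyY(hsb_to_rgb(*config.green_hsb))
    rows = []
    idx = 0
    for Td in (19, 27):
        for Ta in (19, 27):
            for sex in ("F", "M"):
                for k in range(config.n_wings_per_cell):
                    idx += 1
                    params = WingSimParams(pixel_noise_sd=config.pixel_noise_sd, seed=seed + idx)
                    wing = generate_wing_image(params, Td, sex)
                    raw = wing.image ** (1.0 / config.scanner_gamma)  # emulated scanner response
                    linear = apply_calibration(raw, curve)
                    profile = sample_transect(linear, wing.landmarks)
                    row = {"individual": f"W{idx:04d}", "sex": sex, "Td": Td, "Ta": Ta}
                    for cs in internal_contrast(profile, wing.boundaries):
                        row[f"contrast_{cs.element}"] = cs.distance
                    row["crypsis_brown"] = crypsis_score(profile, brown).score
                    row["crypsis_green"] = crypsis_score(profile, green).score
                    rows.append(row)
    return pd.DataFrame(rows)


def _analyze_binomial(response: pd.DataFrame, nsim: int, seed: int) -> dict:
    """BIC selection, per-term LRT (+ bootstrap), post-hoc letters, 1:1 tests."""
    full = MixedModelSpec(fixed=FULL_FIXED, random=("cohort", "timepoint"))
    selected, trace = backward_select_bic(response, full)
    term_rows = []
    for term in selected.spec.removable_terms():
        reduced_fit = fit_glmm(response, selected.spec.drop(term))
        if nsim > 0:
            tr = parametric_bootstrap_p(selected, reduced_fit, nsim=nsim, seed=seed)
        else:
            tr = lrt(selected, reduced_fit)
        term_rows.append(
            {
                "term": ":".join(term),
                "chisq": tr.statistic,
                "df": tr.df,
                "p_lrt": tr.p_lrt,
                "p_boot": tr.p_boot if nsim > 0 else np.nan,
            }
        )
    factors = sorted({f for t in selected.spec.fixed for f in t}) or None
    posthoc = posthoc_pairwise(selected, factors) if factors else None
    even_rows = []
    for (Td, Ta, sex), grp in response.groupby(["Td", "Ta", "Sex"], observed=True):
        s, f = int(grp["successes"].sum()), int(grp["failures"].sum())
        even_rows.append(
            {"Td": Td, "Ta": Ta, "Sex": sex, "successes": s, "failures": f, "p_even": test_vs_even(s, f)}
        )
    return {
        "selected": selected,
        "trace": trace,
        "terms": pd.DataFrame(term_rows),
        "posthoc": posthoc,
        "even": pd.DataFrame(even_rows),
    }


def analyze_behavior(cohorts: pd.DataFrame, nsim: int, seed: int) -> dict:
    pref = build_preference_response(cohorts)
    act = build_activity_response(cohorts)
    seeds = derive_seeds(seed, 2)
    return {
        "preference": _analyze_binomial(pref, nsim, seeds[0]),
        "activity": _analyze_binomial(act, nsim, seeds[1]),
    }


def analyze_pigmentation(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-score-variable F tests for Td, Ta, Sex (no random term: OLS ML)."""
    spec0 = MixedModelSpec(
        response="score", fixed=(("Td",), ("Ta",), ("Sex",)), random=(), family="gaussian"
    )
    rows = []
    score_cols = [c for c in scores.columns if c.startswith(("contrast_", "crypsis_"))]
    for col in score_cols:
        dat = scores.rename(columns={col: "score", "sex": "Sex"})
        ft = lmm_term_ftests(dat, spec0)
        ft.insert(0, "response", col)
        rows.append(ft)
    return pd.concat(rows, ignore_index=True)


def _write_df(df: pd.DataFrame, path: Path, force: bool) -> None:
    if path.exists() and not force:
        old = path.read_text()
        new = df.to_csv(index=False, float_format="%.10g")
        if old != new:
            raise FileExistsError(f"{path} exists with different content; use force to overwrite")
    path.write_text(df.to_csv(index=False, float_format="%.10g"))


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute calibration, wing scoring and all three analyses; write outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed_std, seed_wings, seed_cohorts, seed_analysis = derive_seeds(config.seed, 4)

    logger.info("stage: calibration")
    try:
        standards = generate_calibration_standards(
            true_gamma=config.scanner_gamma, n_levels=10, noise_sd=0.002, seed=seed_std
        )
        curve = fit_calibration(standards, degree=config.calibration_degree)
        curve.to_json(out / "curve.json")
    except Exception as exc:
        raise RuntimeError(f"stage calibration failed: {exc}") from exc

    logger.info("stage: wing scoring")
    try:
        scores = score_wings(config, seed_wings, curve)
        _write_df(scores, out / "scores.csv", config.force)
    except Exception as exc:
        raise RuntimeError(f"stage scoring failed: {exc}") from exc

    logger.info("stage: cohorts")
    try:
        cp = CohortSimParams(
            n_cohorts_per_cell=config.n_cohorts_per_cell,
            sigma_cohort=config.sigma_cohort,
            sigma_timepoint=config.sigma_timepoint,
            preference_effects=dict(config.preference_effects),
            activity_effects=dict(config.activity_effects),
            seed=seed_cohorts,
        )
        cohorts = generate_cohort_series(cp)
        _write_df(cohorts, out / "cohorts.csv", config.force)
    except Exception as exc:
        raise RuntimeError(f"stage cohorts failed: {exc}") from exc

    logger.info("stage: analysis")
    try:
        behavior = analyze_behavior(cohorts, config.nsim, seed_analysis)
        pigment = analyze_pigmentation(scores)
        for role in ("preference", "activity"):
            block = behavior[role]
            _write_df(block["terms"], out / f"{role}_terms.csv", config.force)
            _write_df(block["even"], out / f"{role}_even.csv", config.force)
            if block["posthoc"] is not None:
                ph = block["posthoc"].copy()
                letters = ph.attrs["letters"]
                pd.DataFrame(
                    {"group": list(letters), "letters": list(letters.values())}
                ).to_csv(out / f"{role}_letters.csv", index=False)
                _write_df(ph, out / f"{role}_posthoc.csv", config.force)
        _write_df(pigment, out / "pigment_terms.csv", config.force)
    except Exception as exc:
        raise RuntimeError(f"stage analysis failed: {exc}") from exc

    manifest = {
        "wingcrypsis_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "derived_seeds": {
            "standards": seed_std,
            "wings": seed_wings,
            "cohorts": seed_cohorts,
            "analysis": seed_analysis,
        },
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    pref_sel = behavior["preference"]["selected"]
    summary_lines = [
        f"wingcrypsis run (seed {config.seed}, config {manifest['config_hash']})",
        "",
        "Preference model (selected by BIC): " + ", ".join(":".join(t) for t in pref_sel.spec.fixed),
        pref_sel.summary(),
        "",
        "Activity model (selected by BIC): "
        + ", ".join(":".join(t) for t in behavior["activity"]["selected"].spec.fixed),
        behavior["activity"]["selected"].summary(),
        "",
        "Mean crypsis (distance to brown patch) by Td: "
        + scores.groupby("Td")["crypsis_brown"].mean().round(4).to_string().replace("\n", "; "),
    ]
    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    return {"behavior": behavior, "pigment": pigment, "scores": scores, "manifest": manifest}


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------


def make_figures(results_dir, out_dir=None) -> list:
    """Group-mean figures with per-cohort points and post-hoc letters.

    Reads the CSV outputs of :func:`run_full_pipeline` and renders one
    figure per analysis (contrast, crypsis, preference, activity).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results_dir = Path(results_dir)
    out_dir = Path(out_dir) if out_dir else results_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    scores_path = results_dir / "scores.csv"
    cohorts_path = results_dir / "cohorts.csv"
    if not scores_path.exists() or not cohorts_path.exists():
        raise FileNotFoundError("results directory lacks scores.csv/cohorts.csv")
    scores = pd.read_csv(scores_path)
    cohorts = pd.read_csv(cohorts_path)
    if scores.empty or cohorts.empty:
        raise ValueError("empty results; nothing to plot")
    made = []

    # contrast per element by Td (Fig 1C-style)
    elements = [c for c in scores.columns if c.startswith("contrast_")]
    fig, ax = plt.subplots(figsize=(7, 4))
    for i, el in enumerate(elements):
        for j, td in enumerate((19, 27)):
            vals = scores.loc[scores.Td == td, el]
            x = i + (j - 0.5) * 0.3
            ax.scatter(np.full(len(vals), x) + np.random.default_rng(0).normal(0, 0.03, len(vals)),
                       vals, s=8, alpha=0.5, color="C0" if td == 19 else "C3")
            ax.hlines(vals.mean(), x - 0.12, x + 0.12, color="k")
    ax.set_xticks(range(len(elements)))
    ax.set_xticklabels([e.replace("contrast_", "") for e in elements], rotation=20)
    ax.set_ylabel("internal contrast (CIE-xy distance)")
    fig.tight_layout()
    path = out_dir / "fig_contrast.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    made.append(path)

    # crypsis by group (Fig 1D-style)
    fig, ax = plt.subplots(figsize=(6, 4))
    groups = list(scores.groupby(["Td", "Ta", "sex"], observed=True))
    for i, ((td, ta, sex), grp) in enumerate(groups):
        ax.scatter(np.full(len(grp), i) + np.random.default_rng(1).normal(0, 0.05, len(grp)),
                   grp["crypsis_brown"], s=8, alpha=0.5)
        ax.hlines(grp["crypsis_brown"].mean(), i - 0.2, i + 0.2, color="k")
    ax.set_xticks(range(len(groups)))
    ax.set_xticklabels([f"{td}|{ta}|{s}" for (td, ta, s), _ in groups], rotation=45, fontsize=7)
    ax.set_ylabel("crypsis score (mean distance to brown patch)")
    fig.tight_layout()
    path = out_dir / "fig_crypsis.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    made.append(path)

    # behavioral panels with letters (Fig 2-style)
    for role, scol, fcol in (
        ("preference", "arrivals_brown", "arrivals_green"),
        ("activity", "relocated", "stationary"),
    ):
        letters_path = results_dir / f"{role}_letters.csv"
        letters = {}
        if letters_path.exists():
            ldf = pd.read_csv(letters_path)
            letters = dict(zip(ldf["group"], ldf["letters"]))
        later = cohorts.dropna(subset=[scol, fcol])
        per_cohort = later.groupby(["Td", "Ta", "sex", "cohort_id"], observed=True).agg(
            s=(scol, "sum"), f=(fcol, "sum")
        )
        per_cohort["p"] = per_cohort["s"] / (per_cohort["s"] + per_cohort["f"])
        fig, ax = plt.subplots(figsize=(7, 4))
        cells = list(per_cohort.groupby(["Td", "Ta", "sex"], observed=True))
        for i, ((td, ta, sex), grp) in enumerate(cells):
            ax.scatter(np.full(len(grp), i) + np.random.default_rng(2).normal(0, 0.05, len(grp)),
                       grp["p"], s=12, alpha=0.6)
            ax.hlines(grp["p"].mean(), i - 0.2, i + 0.2, color="k")
            # letters are keyed by the factors kept in the selected model
            for key, lab in letters.items():
                kv = dict(part.split("=") for part in key.split("|"))
                if all(str(kv.get(f, "")) == str(v) for f, v in (("Td", td), ("Ta", ta), ("Sex", sex)) if f in kv):
                    ax.text(i, 1.04, lab, ha="center", fontsize=8)
                    break
        ax.set_ylim(0, 1.1)
        ax.axhline(0.5, ls=":", color="gray")
        ax.set_xticks(range(len(cells)))
        ax.set_xticklabels([f"{td}|{ta}|{s}" for (td, ta, s), _ in cells], rotation=45, fontsize=7)
        ax.set_ylabel(
            "P(relocating to brown)" if role == "preference" else "P(relocating)"
        )
        fig.tight_layout()
        path = out_dir / f"fig_{role}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        made.append(path)
    return made
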
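"""End-to-end orchestration: cohort -> metrics -> HMM -> RL -> correlations
-> sparse CCA, with provenance and CSV/JSON report emission.

Every stage is driven by one :class:`PipelineConfig` and a master seed, so
a run is byte-reproducible from its config.  Stage failures on individual
subjects become missing flags, never exclusions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior_metrics import FEATURE_COLUMNS, build_profile, profiles_frame
from .cohort_stats import fdr_adjust, spearman_with_ci
from .explore_hmm import explore_metrics, fit_baum_welch
from .rl_models import compare_models, fit_mle
from .scca import SCCAInputs, permutation_test, scca_fit, tune_penalties
from .task_sim import (Cohort, CohortConfig, ChoiceData, ItemMatrix, N_ITEMS,
                       generate_cohort, write_cohort)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "load_cohort"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Settings for one full analysis run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    # HMM stage
    hmm_restarts: int = 10
    hmm_tol: float = 1e-6
    hmm_max_iter: int = 500
    # RL stage
    run_rl: bool = True
    rl_restarts: int = 30
    # sCCA stage
    run_scca: bool = True
    tune_scca: bool = False
    scca_scales: tuple = (1.0, 0.9)
    scca_components: int = 3
    scca_folds: int = 10
    scca_resamples: int = 10
    n_perm: int = 5000
    # misc
    output_dir: str | None = None
    seed: int = 0


@dataclass
class RunReport:
    """All tables and fitted objects from one pipeline run."""

    features: pd.DataFrame
    hmm_table: pd.DataFrame
    rl_table: pd.DataFrame | None
    model_comparison: pd.DataFrame | None
    delta_aic: float | None
    correlations: pd.DataFrame
    scca: object | None
    subscales: pd.DataFrame
    provenance: dict


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return {k: v for k, v in vars(o).items()}
    blob = json.dumps(config, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _hmm_stage(cohort: Cohort, config: PipelineConfig, seeds):
    fits, rows = [], []
    for data, seed in zip(cohort.subjects, seeds):
        fit = fit_baum_welch(data, n_restarts=config.hmm_restarts,
                             tol=config.hmm_tol,
                             max_iter=config.hmm_max_iter, seed=seed)
        em = explore_metrics(fit)
        fits.append(fit)
        rows.append({
            "subject": data.subject_id,
            "a": fit.params.a, "b": fit.params.b,
            "log_likelihood": fit.log_likelihood,
            "p_explore": em.p_explore,
            "p_explore_given_explore": em.p_explore_given_explore,
            "p_exploit_given_exploit": em.p_exploit_given_exploit,
        })
    return fits, pd.DataFrame(rows).set_index("subject")


def _rl_stage(cohort: Cohort, config: PipelineConfig, seeds):
    fits_rl, fits_rlck, rows = [], [], []
    for data, seed in zip(cohort.subjects, seeds):
        f_rl = fit_mle("RL", data, n_restarts=config.rl_restarts, seed=seed)
        f_ck = fit_mle("RLCK", data, n_restarts=config.rl_restarts,
                       seed=seed + 1)
        fits_rl.append(f_rl)
        fits_rlck.append(f_ck)
        for f in (f_rl, f_ck):
            rows.append({
                "subject": f.subject_id, "model": f.model,
                "alpha": f.alpha, "beta": f.beta, "alpha_ck": f.alpha_ck,
                "nll": f.nll, "aic": f.aic, "converged": f.converged,
            })
    table, delta = compare_models(fits_rl, fits_rlck)
    return pd.DataFrame(rows), table, delta, fits_rlck


def _correlation_stage(subscales: pd.DataFrame, behavior: pd.DataFrame):
    """Spearman correlation of every subscale sum with every behavioral
    column, BH-FDR adjusted across the whole table."""
    rows = []
    for sub in ("aloof", "rigid", "pragmatic"):
        for col in behavior.columns:
            y = behavior[col].to_numpy(dtype=float)
            try:
                rep = spearman_with_ci(subscales[sub].to_numpy(dtype=float),
                                       y, x_name=sub, y_name=col)
            except ValueError:
                continue
            rows.append({
                "subscale": sub, "metric": col, "rho": rep.rho,
                "ci_low": rep.ci_low, "ci_high": rep.ci_high,
                "p": rep.p_value, "n_used": rep.n_used, "df": rep.df,
            })
    table = pd.DataFrame(rows)
    if len(table):
        table["p_fdr"] = fdr_adjust(table["p"].to_numpy())
    return table


def run_pipeline(config: PipelineConfig, cohort: Cohort | None = None
                 ) -> RunReport:
    """Execute the full analysis and return a :class:`RunReport`.

    Generates a cohort from ``config.cohort`` unless one is supplied
    (e.g. loaded from disk via :func:`load_cohort`), fits the explore/
    exploit HMM and (optionally) the RL models per subject, assembles the
    nine-feature table, correlates each questionnaire subscale sum with
    every behavioral quantity, and runs sparse CCA of the 36 items against
    the nine features with a permutation test.  Writes all tables under
    ``config.output_dir`` when set.
    """
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = ss.spawn(4)
    if cohort is None:
        cohort = generate_cohort(config.cohort)

    hmm_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                 stage_seeds[0].spawn(cohort.n_subjects)]
    hmm_fits, hmm_table = _hmm_stage(cohort, config, hmm_seeds)

    profiles = []
    for data, walk, fit in zip(cohort.subjects, cohort.walks or
                               [None] * cohort.n_subjects, hmm_fits):
        profiles.append(build_profile(data, walk=walk, hmm_fit=fit))
    features = profiles_frame(profiles)

    rl_table = comparison = None
    delta_aic = None
    if config.run_rl:
        rl_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                    stage_seeds[1].spawn(cohort.n_subjects)]
        rl_table, comparison, delta_aic, fits_rlck = _rl_stage(
            cohort, config, rl_seeds)

    subscales = cohort.items.subscale_sums()
    subscales.index = features.index

    behavior = features.copy()
    behavior["p_explore_given_explore"] = hmm_table[
        "p_explore_given_explore"].to_numpy()
    behavior["p_exploit_given_exploit"] = hmm_table[
        "p_exploit_given_exploit"].to_numpy()
    if config.run_rl:
        ck = rl_table[rl_table["model"] == "RLCK"].set_index("subject")
        behavior["rl_alpha"] = ck["alpha"].reindex(features.index).to_numpy()
        behavior["rl_beta"] = ck["beta"].reindex(features.index).to_numpy()
        behavior["rl_alpha_ck"] = ck["alpha_ck"].reindex(
            features.index).to_numpy()
    correlations = _correlation_stage(subscales, behavior)

    scca_result = None
    if config.run_scca:
        # sCCA needs complete rows; impute the column median for the rare
        # degenerate-subject NaNs so nobody is excluded
        F = features[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        med = np.nanmedian(F, axis=0)
        idx = np.where(np.isnan(F))
        F[idx] = np.take(med, idx[1])
        inputs = SCCAInputs(cohort.items.scores.astype(float), F,
                            b_names=[f"item_{j+1:02d}" for j in
                                     range(N_ITEMS)],
                            e_names=list(FEATURE_COLUMNS))
        scales = config.scca_scales
        if config.tune_scca:
            s1, s2, _ = tune_penalties(
                inputs, k_folds=config.scca_folds,
                n_resamples=config.scca_resamples,
                seed=int(stage_seeds[2].generate_state(1)[0] % (2**31)))
            scales = (s1, s2)
        scca_result = scca_fit(inputs, scales[0], scales[1],
                               n_components=config.scca_components)
        if scca_result.components and config.n_perm > 0:
            permutation_test(
                inputs, scca_result, n_perm=config.n_perm,
                seed=int(stage_seeds[3].generate_state(1)[0] % (2**31)))

    provenance = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "feature_definitions": {
            "p_explore": "fraction of trials Viterbi-labeled explore",
            "exploration_potential":
                "fitted exploit-to-explore transition probability a",
        },
    }
    report = RunReport(features=features, hmm_table=hmm_table,
                       rl_table=rl_table, model_comparison=comparison,
                       delta_aic=delta_aic, correlations=correlations,
                       scca=scca_result, subscales=subscales,
                       provenance=provenance)
    if config.output_dir is not None:
        _write_report(report, cohort, config)
    return report


def _write_report(report: RunReport, cohort: Cohort,
                  config: PipelineConfig):
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort(cohort, out / "cohort")
    report.features.to_csv(out / "features.csv")
    report.hmm_table.to_csv(out / "hmm_fits.csv")
    if report.rl_table is not None:
        report.rl_table.to_csv(out / "rl_fits.csv", index=False)
        report.model_comparison.to_csv(out / "model_comparison.csv",
                                       index=False)
    report.correlations.to_csv(out / "correlations.csv", index=False)
    summary = dict(report.provenance)
    if report.delta_aic is not None:
        summary["delta_aic"] = report.delta_aic
    if report.scca is not None and report.scca.components:
        summary["scca"] = {
            "penalties": list(report.scca.penalties),
            "canonical_correlations":
                report.scca.canonical_correlations.tolist(),
            "perm_p": None if report.scca.perm_p is None else
                report.scca.perm_p.tolist(),
            "perm_p_fdr": None if report.scca.perm_p_fdr is None else
                report.scca.perm_p_fdr.tolist(),
        }
        weights = pd.DataFrame({
            "variable": (report.scca.components[0].x.size * ["item"]
                         + report.scca.components[0].y.size * ["behavior"]),
            "name": [f"item_{j+1:02d}" for j in
                     range(report.scca.components[0].x.size)]
                    + list(FEATURE_COLUMNS),
            "weight": np.concatenate([report.scca.components[0].x,
                                      report.scca.components[0].y]),
            "loading": np.concatenate([report.scca.components[0].b_loadings,
                                       report.scca.components[0].e_loadings]),
        })
        weights.to_csv(out / "scca_component1.csv", index=False)
    (out / "summary.json").write_text(json.dumps(summary, indent=2))


def load_cohort(choice_csv, item_csv) -> Cohort:
    """Load a cohort from long-format choice and item CSVs.

    Walks are unavailable for loaded cohorts, so walk-dependent metrics
    (reward above chance) come back NaN.  Malformed rows raise with their
    position; misaligned subject sets are a hard error.
    """
    choices = pd.read_csv(choice_csv)
    items = pd.read_csv(item_csv)
    required = {"subject", "trial", "choice", "reward"}
    if not required.issubset(choices.columns):
        raise ValueError(f"choice file must have columns {sorted(required)}")
    has_rt = "rt" in choices.columns and choices["rt"].notna().all()

    item_cols = [c for c in items.columns if c.startswith("item_")]
    if len(item_cols) != N_ITEMS:
        raise ValueError(f"item file must have {N_ITEMS} item_* columns, "
                         f"found {len(item_cols)}")
    bad = ~items[item_cols].isin(range(1, 7))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"item score out of range 1..6 at subject row {r}, "
            f"column {item_cols[c]!r}")

    subj_choice = list(dict.fromkeys(choices["subject"]))
    subj_items = list(items["subject"]) if "subject" in items.columns else []
    if subj_items and subj_choice != subj_items:
        raise ValueError("subject sets in choice and item files do not "
                         "align")

    subjects = []
    for sid, grp in choices.groupby("subject", sort=False):
        grp = grp.sort_values("trial")
        if not np.isin(grp["reward"].to_numpy(), (0, 1)).all():
            row = grp.index[~grp["reward"].isin((0, 1))][0]
            raise ValueError(f"non-binary reward at input row {row}")
        subjects.append(ChoiceData(
            choices=grp["choice"].to_numpy(),
            rewards=grp["reward"].to_numpy(dtype=float),
            rts=grp["rt"].to_numpy(dtype=float) if has_rt else None,
            subject_id=str(sid)))
    item_matrix = ItemMatrix(items[item_cols].to_numpy())
    return Cohort(subjects=subjects, walks=None, items=item_matrix,
                  traits=np.full((len(subjects), 3), np.nan),
                  params=pd.DataFrame(), config=None)
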
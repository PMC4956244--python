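"""End-to-end cohort simulation and analysis.

Builds the trial grids, simulates a cohort of heterogeneous Bayesian
observers in a regular and an irregular temporal environment, and runs the
two analysis tracks: regularity-judgment proportions with two-criteria
fits, and TOJ-based PSS/JND estimation with the practice-phase exclusion
rule and the regularisation index.

Sign conventions.  The design stores ``soa_ms`` = flash onset − final tone
onset.  TOJ psychometric curves are analysed on the axis
``tone_minus_flash_ms`` = −``soa_ms`` with 'light_first' as the positive
response, so the proportion rises 0 → 1 across the padded range and a
positive PSS means the light had to be presented before the sound to be
perceived simultaneous.  Under this convention the regularisation index
100 × (PSS_late − PSS_early) / 80 is positive when the perceived early/late
separation is compressed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import design
from .observer import ObserverParams, simulate_session
from .psychometrics import aggregate, probit_bounded, sk_estimate
from .regularity_model import fit_two_criteria

#: (mean, sd) of each observer parameter across a cohort; sd 0 fixes it.
DEFAULT_OBSERVER_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "sensory_sd": (20.0, 4.0),
    "initial_prior_sd": (150.0, 20.0),
    "interval_sd": (30.0, 5.0),
    "env_learning_rate": (0.1, 0.0),
    "criterion_early": (-100.0, 15.0),
    "criterion_late": (100.0, 15.0),
    "criterion_sd_early": (30.0, 5.0),
    "criterion_sd_late": (30.0, 5.0),
    "visual_latency_sd": (40.0, 8.0),
    "lapse_rate": (0.02, 0.0),
}

# lower/upper truncation of the cohort draws, per parameter
_PARAM_TRUNCATION: dict[str, tuple[float, float]] = {
    "sensory_sd": (1.0, np.inf),
    "initial_prior_sd": (1.0, np.inf),
    "interval_sd": (0.0, np.inf),
    "env_learning_rate": (0.0, 1.0),
    "criterion_early": (-np.inf, -1.0),
    "criterion_late": (1.0, np.inf),
    "criterion_sd_early": (1.0, np.inf),
    "criterion_sd_late": (1.0, np.inf),
    "visual_latency_sd": (1.0, np.inf),
    "lapse_rate": (0.0, 0.5),
}

_ENVIRONMENTS = ("regular", "irregular")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort sizes, observer-parameter distributions, and analysis knobs.

    Observers per group default to the study sizes (10 for the regularity
    experiment, 12 for the TOJ experiment).  The exclusion thresholds are
    the JND ceilings above which an observer's data are dropped.
    """

    n_observers_per_group: int = 12
    exp1_observers_per_group: int = 10
    observer_distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OBSERVER_DISTRIBUTIONS)
    )
    ioi: float = design.BASE_IOI_MS
    exp1_repetitions: int = 8
    exp2_repetitions: int = 10
    practice_repetitions: int = 6
    practice_jnd_max: float = 250.0
    test_jnd_max: float = 200.0
    sk_lower_bound: float = -250.0
    sk_upper_bound: float = 250.0
    practice_sk_bound: float = 400.0

    def __post_init__(self) -> None:
        if self.n_observers_per_group < 1 or self.exp1_observers_per_group < 1:
            raise ValueError("need at least one observer per group")
        if self.practice_jnd_max <= 0 or self.test_jnd_max <= 0:
            raise ValueError("exclusion thresholds must be positive")

    @classmethod
    def from_dict(cls, cfg: dict) -> "CohortConfig":
        """Build from the sectioned config layout ([design]/[observer]/[cohort]/[analysis])."""
        kw: dict = {}
        d = cfg.get("design", {})
        kw.update({k: d[k] for k in (
            "ioi", "exp1_repetitions", "exp2_repetitions",
            "practice_repetitions") if k in d})
        c = cfg.get("cohort", {})
        kw.update({k: c[k] for k in (
            "n_observers_per_group", "exp1_observers_per_group") if k in c})
        a = cfg.get("analysis", {})
        kw.update({k: a[k] for k in (
            "practice_jnd_max", "test_jnd_max", "sk_lower_bound",
            "sk_upper_bound", "practice_sk_bound") if k in a})
        obs = cfg.get("observer", {})
        if obs:
            dists = dict(DEFAULT_OBSERVER_DISTRIBUTIONS)
            for name, ms in obs.items():
                if name not in dists:
                    raise KeyError(f"unknown observer parameter {name!r}")
                dists[name] = (float(ms[0]), float(ms[1]))
            kw["observer_distributions"] = dists
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def flat_prior_config(**overrides) -> CohortConfig:
    """A null cohort whose predictions never inform perception.

    Prediction uncertainty is made effectively infinite and learning is
    disabled, so the sensory weight is 1 and no regularisation can occur.
    """
    dists = dict(DEFAULT_OBSERVER_DISTRIBUTIONS)
    dists["initial_prior_sd"] = (1e6, 0.0)
    dists["interval_sd"] = (1e6, 0.0)
    dists["env_learning_rate"] = (0.0, 0.0)
    return CohortConfig(observer_distributions=dists, **overrides)


def draw_observer_params(
    config: CohortConfig, rng: np.random.Generator
) -> ObserverParams:
    """One observer's parameters from truncated-Gaussian cohort distributions."""
    values: dict[str, float] = {}
    for name, (mean, sd) in config.observer_distributions.items():
        lo, hi = _PARAM_TRUNCATION[name]
        x = mean if sd == 0 else rng.normal(mean, sd)
        for _ in range(100):
            if lo <= x <= hi:
                break
            x = rng.normal(mean, sd)
        values[name] = float(np.clip(x, lo, hi))
    if values["criterion_early"] >= values["criterion_late"]:
        values["criterion_early"] = values["criterion_late"] - 1.0
    return ObserverParams(**values)


def regularisation_index(
    pss_early: float, pss_late: float, anisochrony_span: float = 80.0
) -> float:
    """PSS(late) − PSS(early) as a percentage of their physical separation.

    Positive values mean the perceived early/late separation is compressed
    toward regularity; 100% is complete regularisation.
    """
    if anisochrony_span <= 0:
        raise ValueError("anisochrony span must be positive")
    return 100.0 * (pss_late - pss_early) / anisochrony_span


def apply_exclusion(
    sk_estimates: pd.DataFrame, config: CohortConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split SK estimates into retained and excluded rows.

    A row is excluded when its JND is strictly above the threshold for its
    phase (250 ms practice, 200 ms test by default); a JND exactly at the
    threshold is retained.
    """
    if "jnd_ms" not in sk_estimates.columns:
        raise KeyError("sk_estimates must have a jnd_ms column")
    if len(sk_estimates) == 0:
        return sk_estimates.copy(), sk_estimates.copy()
    phase = sk_estimates.get("phase", pd.Series("test", index=sk_estimates.index))
    limit = phase.map(
        {"practice": config.practice_jnd_max}
    ).fillna(config.test_jnd_max)
    mask = sk_estimates["jnd_ms"] > limit
    return sk_estimates[~mask].copy(), sk_estimates[mask].copy()


def _session_seeds(master_seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(master_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _cohort(config, seed, environments, n_per_group):
    """Draw observers and session seeds for both environment groups."""
    rng = np.random.default_rng(seed)
    roster = []
    for env in environments:
        for i in range(n_per_group):
            params = draw_observer_params(config, rng)
            roster.append((f"{env}_{i:02d}", env, params))
    seeds = _session_seeds(
        int(np.random.default_rng(seed + 1).integers(0, 2**31 - 1)),
        len(roster),
    )
    return roster, seeds


def run_experiment1(config: CohortConfig, seed: int) -> dict[str, pd.DataFrame]:
    """Simulate the regularity-judgment experiment for both groups.

    Returns raw responses, per-observer and group-mean proportion tables
    (with probit-transformed proportions), and per-observer two-criteria
    fits on the isochronous-context (jitter 0) trials.
    """
    roster, seeds = _cohort(
        config, seed, _ENVIRONMENTS, config.exp1_observers_per_group
    )
    responses = []
    fits = []
    for (obs_id, env, params), s in zip(roster, seeds):
        grid = design.shuffle_grid(
            design.build_exp1_grid(env, config.exp1_repetitions), s
        )
        table = simulate_session(
            grid, params, seed=s, ioi=config.ioi, observer_id=obs_id
        )
        responses.append(table)
        cell = table[table["jitter_level_ms"] == 0.0]
        fit = fit_two_criteria(
            aggregate(cell, "anisochrony_ms", "regular"), seed=s
        )
        fits.append(
            {
                "observer_id": obs_id, "environment": env,
                "c_early_ms": fit.c_early, "c_late_ms": fit.c_late,
                "sigma_early_ms": fit.sigma_early,
                "sigma_late_ms": fit.sigma_late,
                "nll": fit.neg_log_likelihood, "converged": fit.converged,
            }
        )
    responses = pd.concat(responses, ignore_index=True)

    per_obs = (
        responses.assign(regular=responses["response"] == "regular")
        .groupby(
            ["environment", "observer_id", "jitter_level_ms",
             "anisochrony_ms"], sort=True,
        )
        .agg(n_trials=("regular", "size"), n_regular=("regular", "sum"))
        .reset_index()
    )
    per_obs["p_regular"] = per_obs["n_regular"] / per_obs["n_trials"]
    per_obs["probit_p_regular"] = probit_bounded(per_obs["p_regular"].values)

    group = (
        per_obs.groupby(
            ["environment", "jitter_level_ms", "anisochrony_ms"], sort=True
        )
        .agg(
            p_regular=("p_regular", "mean"),
            probit_p_regular=("probit_p_regular", "mean"),
            n_observers=("observer_id", "nunique"),
        )
        .reset_index()
    )
    return {
        "responses": responses,
        "proportions_per_observer": per_obs,
        "proportions_group": group,
        "two_criteria_fits": pd.DataFrame(fits),
    }


def _toj_sk(table: pd.DataFrame, lower: float, upper: float):
    """SK estimate of a TOJ table on the tone-minus-flash axis."""
    data = aggregate(
        table.assign(tone_minus_flash_ms=-table["soa_ms"]),
        "tone_minus_flash_ms",
        "light_first",
    )
    return sk_estimate(data, lower_bound=lower, upper_bound=upper)


def run_experiment2(config: CohortConfig, seed: int) -> dict[str, pd.DataFrame]:
    """Simulate the TOJ experiment: practice, exclusion, test, summaries.

    Each observer first runs the practice phase (single tone + flash);
    observers whose practice JND exceeds the ceiling are excluded from the
    test phase.  Test-phase PSS/JND are estimated per jitter × anisochrony
    cell (pooling the nine SOAs), then observers whose mean test JND
    exceeds its ceiling are dropped, and the per-jitter regularisation
    index summarises the group-level PSS difference between late and early
    deviants.
    """
    roster, seeds = _cohort(
        config, seed, _ENVIRONMENTS, config.n_observers_per_group
    )
    practice_rows = []
    for (obs_id, env, params), s in zip(roster, seeds):
        grid = design.shuffle_grid(
            design.build_practice_grid(config.practice_repetitions, env), s
        )
        table = simulate_session(
            grid, params, seed=s, ioi=config.ioi, observer_id=obs_id
        )
        est = _toj_sk(
            table, -config.practice_sk_bound, config.practice_sk_bound
        )
        practice_rows.append(
            {
                "observer_id": obs_id, "environment": env,
                "phase": "practice", "pss_ms": est.pss, "jnd_ms": est.jnd,
                "session_seed": s,
            }
        )
    practice = pd.DataFrame(practice_rows)
    practice_retained, practice_excluded = apply_exclusion(practice, config)
    kept = set(practice_retained["observer_id"])

    sk_rows = []
    for (obs_id, env, params), s in zip(roster, seeds):
        if obs_id not in kept:
            continue
        grid = design.shuffle_grid(
            design.build_exp2_grid(env, config.exp2_repetitions), s + 1
        )
        table = simulate_session(
            grid, params, seed=s + 1, ioi=config.ioi, observer_id=obs_id
        )
        for (jit, aniso), cell in table.groupby(
            ["jitter_level_ms", "anisochrony_ms"], sort=True
        ):
            est = _toj_sk(cell, config.sk_lower_bound, config.sk_upper_bound)
            sk_rows.append(
                {
                    "observer_id": obs_id, "environment": env,
                    "phase": "test", "jitter_level_ms": jit,
                    "anisochrony_ms": aniso, "pss_ms": est.pss,
                    "jnd_ms": est.jnd, "monotonized": est.monotonized,
                    "session_seed": s + 1,
                }
            )
    sk_columns = [
        "observer_id", "environment", "phase", "jitter_level_ms",
        "anisochrony_ms", "pss_ms", "jnd_ms", "monotonized", "session_seed",
    ]
    sk = pd.DataFrame(sk_rows, columns=sk_columns)
    if len(sk) == 0:
        empty_summary = pd.DataFrame(
            columns=["environment", "jitter_level_ms", "pss_early_ms",
                     "pss_late_ms", "index_percent", "n_observers"]
        )
        return {
            "practice": practice,
            "practice_excluded": practice_excluded,
            "sk_estimates": sk,
            "test_excluded_observers": sk.iloc[:0][["observer_id"]],
            "per_observer_index": empty_summary.drop(columns=["n_observers"]),
            "regularisation_summary": empty_summary,
            "jnd_table": pd.DataFrame(
                columns=["environment", "jitter_level_ms", "jnd_ms", "n_cells"]
            ),
        }

    # test-phase rule applied per observer on the mean JND across cells
    mean_jnd = sk.groupby(
        ["observer_id", "environment"], sort=True
    )["jnd_ms"].mean().reset_index()
    mean_jnd["phase"] = "test"
    test_retained_obs, test_excluded_obs = apply_exclusion(mean_jnd, config)
    kept_test = set(test_retained_obs["observer_id"])
    sk_retained = sk[sk["observer_id"].isin(kept_test)].copy()

    wide = sk_retained.pivot_table(
        index=["environment", "observer_id", "jitter_level_ms"],
        columns="anisochrony_ms", values="pss_ms",
    ).reset_index()
    wide = wide.rename(columns={-40.0: "pss_early_ms", 40.0: "pss_late_ms"})
    wide["index_percent"] = regularisation_index(
        wide["pss_early_ms"], wide["pss_late_ms"]
    )
    summary = (
        wide.groupby(["environment", "jitter_level_ms"], sort=True)
        .agg(
            pss_early_ms=("pss_early_ms", "mean"),
            pss_late_ms=("pss_late_ms", "mean"),
            index_percent=("index_percent", "mean"),
            n_observers=("observer_id", "nunique"),
        )
        .reset_index()
    )
    jnd_table = (
        sk_retained.groupby(["environment", "jitter_level_ms"], sort=True)
        .agg(jnd_ms=("jnd_ms", "mean"), n_cells=("jnd_ms", "size"))
        .reset_index()
    )
    return {
        "practice": practice,
        "practice_excluded": practice_excluded,
        "sk_estimates": sk_retained,
        "test_excluded_observers": test_excluded_obs,
        "per_observer_index": wide,
        "regularisation_summary": summary,
        "jnd_table": jnd_table,
    }


def report(
    tables: dict[str, pd.DataFrame],
    outdir,
    config: CohortConfig | None = None,
    seed: int | None = None,
) -> dict[str, str]:
    """Write each table as CSV with stable column order, plus a run log.

    The log records the master seed, every session seed appearing in the
    tables, the config hash, and the package version.  Deterministic:
    identical (config, seed) inputs produce byte-identical files.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    session_seeds = set()
    for name in sorted(tables):
        frame = tables[name]
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        written[name] = str(path)
        for col in ("seed", "session_seed"):
            if col in frame.columns:
                session_seeds.update(int(s) for s in frame[col].dropna())
    log = {
        "package_version": __version__,
        "master_seed": seed,
        "session_seeds": sorted(session_seeds),
        "config_hash": config.config_hash() if config is not None else None,
        "tables": sorted(tables),
    }
    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True))
    written["run_log"] = str(log_path)
    return written
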
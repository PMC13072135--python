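"""Study orchestration: from raw or simulated cohorts to analysis reports.

``run_study`` executes the full design: a main cohort measured on two
consecutive respirometry days plus a 6-min novel-tank trial (repeatability,
mass–consumption validation, sex x strain ANOVA on RMR, and the
boldness/behavior x RMR correlation screen — the pace-of-life test), and a
fasting manipulation (crossover respirometry, between-groups behavior).
In simulate mode ground truth is carried through to a recovery appendix;
in ingest mode the same analyses run on user-supplied CSV cohorts.

Reports are deterministic given (config, seed): identical runs produce
byte-identical JSON/CSV output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import boldness as bold
from . import respirometry as resp
from . import stats as st
from .simulate import (
    CohortConfig,
    CohortTable,
    GroundTruth,
    cohort_config_from_dict,
    generate_cohort,
)
from .trajectory import extract_profile, profiles_to_frame

__all__ = [
    "StudyConfig",
    "StudyReport",
    "default_study_config",
    "study_config_from_dict",
    "load_study_config",
    "run_study",
    "validate_inputs",
]

BEHAVIOR_METRICS = (
    "bottom_distance",
    "center_distance",
    "distance_traveled",
    "percent_explored",
    "percent_immobile",
    "max_velocity",
)

_FASTING_BEHAVIORS = (
    "bottom_distance",
    "center_distance",
    "distance_traveled",
    "percent_explored",
)


def _paper_design_main() -> CohortConfig:
    return CohortConfig(
        strains=("TU", "WIK"),
        sexes=("female", "male"),
        n_per_cell={
            ("TU", "female"): 30,
            ("TU", "male"): 30,
            ("WIK", "female"): 33,
            ("WIK", "male"): 33,
        },
        fasting="none",
        n_days=2,
    )


def _paper_design_fasting_respirometry() -> CohortConfig:
    return CohortConfig(
        n_per_cell={
            ("TU", "female"): 22,
            ("TU", "male"): 24,
            ("WIK", "female"): 23,
            ("WIK", "male"): 22,
        },
        fasting="crossover",
        simulate_behavior=False,
    )


def _paper_design_fasting_behavior() -> CohortConfig:
    return CohortConfig(
        n_per_cell={
            ("TU", "female"): 15,
            ("TU", "male"): 16,
            ("WIK", "female"): 22,
            ("WIK", "male"): 21,
        },
        n_unfed_per_cell={
            ("TU", "female"): 15,
            ("TU", "male"): 16,
            ("WIK", "female"): 19,
            ("WIK", "male"): 19,
        },
        fasting="between",
        n_days=1,
    )


@dataclass
class StudyConfig:
    """Full study specification.

    Exactly one input mode: ``simulate`` (cohort configs below are used,
    seed mandatory) or ``ingest`` (``paths`` maps block names to cohort
    directories).  Defaults reproduce the published design: 2 strains x
    2 sexes, two consecutive respirometry days, fasting as a crossover
    for respirometry and between groups for behavior.
    """

    mode: str = "simulate"
    seed: int = 0
    alpha: float = 0.05
    n_perm: int = 10000
    n_boot: int = 1000
    analyses: tuple = ("repeatability", "pols_correlations", "fasting")
    cohort: CohortConfig = field(default_factory=_paper_design_main)
    fasting_respirometry: CohortConfig = field(
        default_factory=_paper_design_fasting_respirometry
    )
    fasting_behavior: CohortConfig = field(default_factory=_paper_design_fasting_behavior)
    paths: dict | None = None
    center_convention: str = "horizontal"
    immobility_threshold: float = 1.5

    def validate(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError(f"mode must be 'simulate' or 'ingest', got {self.mode!r}")
        if self.mode == "ingest" and not self.paths:
            raise ValueError("ingest mode requires 'paths'")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


def default_study_config(seed: int = 0) -> StudyConfig:
    return StudyConfig(seed=seed)


def study_config_from_dict(d: dict) -> StudyConfig:
    d = dict(d)
    for key in ("cohort", "fasting_respirometry", "fasting_behavior"):
        if key in d:
            d[key] = cohort_config_from_dict(d[key])
    if "analyses" in d:
        d["analyses"] = tuple(d["analyses"])
    config = StudyConfig(**d)
    config.validate()
    return config


def load_study_config(path) -> StudyConfig:
    """Load a YAML or JSON study configuration file."""
    import yaml

    text = Path(path).read_text()
    return study_config_from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# report


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


@dataclass
class StudyReport:
    """All analysis blocks plus run metadata, QC accounting and a log."""

    meta: dict
    qc: dict
    repeatability: dict | None = None
    mass_correlations: list | None = None
    anova_rmr: dict | None = None
    correlation_screen: list | None = None
    fasting: dict | None = None
    recovery: dict | None = None
    log: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return _as_plain(
            {
                "meta": self.meta,
                "qc": self.qc,
                "repeatability": self.repeatability,
                "mass_correlations": self.mass_correlations,
                "anova_rmr": self.anova_rmr,
                "correlation_screen": self.correlation_screen,
                "fasting": self.fasting,
                "recovery": self.recovery,
            }
        )

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n"
        )
        if self.correlation_screen is not None:
            pd.DataFrame(self.correlation_screen).to_csv(
                out / "correlation_screen.csv", index=False
            )
        if self.mass_correlations is not None:
            pd.DataFrame(self.mass_correlations).to_csv(
                out / "mass_correlations.csv", index=False
            )
        (out / "log.txt").write_text("\n".join(self.log) + "\n")


# ---------------------------------------------------------------------------
# per-cohort processing


def _metabolic_results(table: CohortTable) -> tuple[list, list]:
    results = [resp.compute_rmr(r) for r in table.respirometry]
    excluded = [
        {"fish_id": r.fish_id, "session_day": r.session_day, "reason": r.qc_reason}
        for r in results
        if not r.qc_pass
    ]
    return results, excluded


def _behavior_frame(table: CohortTable, config: StudyConfig) -> pd.DataFrame:
    profiles = [
        extract_profile(
            traj,
            immobility_threshold=config.immobility_threshold,
            center_convention=config.center_convention,
        )
        for _, traj in sorted(table.trajectories.items())
    ]
    return profiles_to_frame(profiles).merge(table.metadata, on="fish_id", how="inner")


def _rmr_frame(results: list, day: int = 1) -> pd.DataFrame:
    df = resp.results_to_frame(results)
    return df[(df["session_day"] == day) & df["qc_pass"]][
        ["fish_id", "o2_consumed", "rmr", "mass_g"]
    ]


# ---------------------------------------------------------------------------
# analysis blocks


def _repeatability_block(table, results, config, seed, log) -> dict:
    block = {}
    meta = table.metadata
    for sex in sorted(meta["sex"].unique()):
        fish = set(meta.loc[meta["sex"] == sex, "fish_id"])
        sex_results = [r for r in results if r.fish_id in fish]
        pairs, dropped = resp.pair_sessions(sex_results)
        if len(pairs) < 5:
            block[sex] = {"n": len(pairs), "note": "too few complete pairs"}
            continue
        corr = st.correlation_auto(
            pairs["o2_consumed_day1"], pairs["o2_consumed_day2"], alpha=config.alpha
        )
        icc = st.icc_oneway(
            pairs["o2_consumed_day1"], pairs["o2_consumed_day2"],
            n_boot=config.n_boot, seed=seed,
        )
        log.append(
            f"repeatability[{sex}]: {corr.method} gate "
            f"(x normal={corr.gate_report['x']['normal']}, "
            f"y normal={corr.gate_report['y']['normal']}), n={corr.n}, "
            f"dropped={sorted(dropped)}"
        )
        block[sex] = {
            "n": corr.n,
            "dropped": sorted(dropped),
            "correlation": corr,
            "icc": icc,
        }
    return block


def _mass_correlation_block(table, results, config, log) -> list:
    rows = []
    day1 = _rmr_frame(results).merge(
        table.metadata[["fish_id", "strain", "sex"]], on="fish_id"
    )
    for (strain, sex), cell in day1.groupby(["strain", "sex"]):
        corr = st.correlation_auto(cell["mass_g"], cell["o2_consumed"], alpha=config.alpha)
        log.append(f"mass~O2[{strain} {sex}]: {corr.method}, n={corr.n}")
        rows.append(
            {
                "strain": strain,
                "sex": sex,
                "method": corr.method,
                "coefficient": corr.coefficient,
                "p_value": corr.p_value,
                "n": corr.n,
            }
        )
    return rows


def _anova_block(table, results, config, seed) -> dict:
    day1 = _rmr_frame(results).merge(
        table.metadata[["fish_id", "strain", "sex"]], on="fish_id"
    )
    res = st.perm_anova_2x2(
        day1["rmr"], day1["sex"], day1["strain"],
        n_perm=config.n_perm, seed=seed, factor_names=("sex", "strain"),
    )
    return {
        "n": int(len(day1)),
        "terms": {
            name: {
                "F": term.F,
                "p_value": term.p_value,
                "eta_squared": term.eta_squared,
                "effect_label": st.classify_effect("eta_squared", term.eta_squared).label,
            }
            for name, term in res.terms.items()
        },
        "n_perm": res.n_perm,
    }


def _correlation_screen_block(behavior, results, config, log) -> list:
    merged = behavior.merge(_rmr_frame(results), on="fish_id", how="inner")
    merged = bold.boldness_index(merged)
    rows = []
    variables = ("boldness_index",) + BEHAVIOR_METRICS
    for (strain, sex), cell in merged.groupby(["strain", "sex"]):
        for var in variables:
            vals = cell[[var, "rmr"]].dropna()
            if len(vals) < 4:
                continue
            if vals[var].nunique() <= 1 or vals["rmr"].nunique() <= 1:
                log.append(
                    f"screen[{strain} {sex}] {var}~rmr: skipped (constant variable)"
                )
                continue
            corr = st.correlation_auto(vals[var], vals["rmr"], alpha=config.alpha)
            if corr.method == "spearman":
                log.append(
                    f"screen[{strain} {sex}] {var}~rmr: spearman fallback "
                    f"(normality rejected)"
                )
            rows.append(
                {
                    "strain": strain,
                    "sex": sex,
                    "variable": var,
                    "method": corr.method,
                    "coefficient": corr.coefficient,
                    "p_value": corr.p_value,
                    "significant": corr.p_value < config.alpha,
                    "n": corr.n,
                }
            )
    if rows:
        adj = st.benjamini_hochberg([r["p_value"] for r in rows])
        for r, q in zip(rows, adj):
            r["p_bh"] = float(q)
    return rows


def _fasting_block(respiro_table, behavior_table, config, seed, log) -> dict:
    block: dict = {}
    # crossover respirometry: per-strain 2x2 (feed x sex) permutation ANOVA
    # on RMR, plus paired fed/unfed tests within each sex x strain cell
    results, excluded = _metabolic_results(respiro_table)
    df = resp.results_to_frame(results)
    df = df[df["qc_pass"]].merge(
        respiro_table.metadata[["fish_id", "strain", "sex"]], on="fish_id"
    )
    anovas, paired = {}, []
    for strain, cell in df.groupby("strain"):
        res = st.perm_anova_2x2(
            cell["rmr"], cell["feed_state"], cell["sex"],
            n_perm=config.n_perm, seed=seed, factor_names=("feed_state", "sex"),
        )
        anovas[strain] = {
            "n_obs": int(len(cell)),
            "terms": {
                name: {
                    "F": t.F,
                    "p_value": t.p_value,
                    "eta_squared": t.eta_squared,
                    "effect_label": st.classify_effect("eta_squared", t.eta_squared).label,
                }
                for name, t in res.terms.items()
            },
        }
    for (strain, sex), cell in df.groupby(["strain", "sex"]):
        wide = cell.pivot_table(index="fish_id", columns="feed_state", values="rmr")
        wide = wide.dropna()
        if len(wide) < 5 or not {"fed", "unfed"} <= set(wide.columns):
            continue
        res = st.two_group_test(
            wide["fed"].to_numpy(), wide["unfed"].to_numpy(),
            paired=True, alpha=config.alpha,
        )
        log.append(f"fasting rmr[{strain} {sex}]: {res.method}, n={len(wide)}")
        paired.append(
            {
                "strain": strain,
                "sex": sex,
                "method": res.method,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n_pairs": int(len(wide)),
                "mean_fed": float(wide["fed"].mean()),
                "mean_unfed": float(wide["unfed"].mean()),
            }
        )
    block["respirometry"] = {
        "anova_by_strain": anovas,
        "paired_tests": paired,
        "qc_excluded": excluded,
    }

    # between-groups behavior: fed vs unfed per cell and behavior
    behavior = _behavior_frame(behavior_table, config)
    rows = []
    for (strain, sex), cell in behavior.groupby(["strain", "sex"]):
        fed = cell[cell["feed_state"] == "fed"]
        unfed = cell[cell["feed_state"] == "unfed"]
        for var in _FASTING_BEHAVIORS:
            y1, y2 = fed[var].dropna(), unfed[var].dropna()
            if min(len(y1), len(y2)) < 3:
                continue
            res = st.two_group_test(y1, y2, alpha=config.alpha)
            if res.method == "mann_whitney":
                log.append(f"fasting behavior[{strain} {sex}] {var}: Mann–Whitney used")
            rows.append(
                {
                    "strain": strain,
                    "sex": sex,
                    "variable": var,
                    "method": res.method,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "cohen_d": res.cohen_d,
                    "effect_label": st.classify_effect("cohen_d", res.cohen_d).label
                    if res.cohen_d is not None
                    else None,
                    "n_fed": res.n1,
                    "n_unfed": res.n2,
                }
            )
    block["behavior"] = rows
    return block


def _recovery_block(truths: dict, tables: dict, behaviors: dict, results: dict) -> dict:
    """Compare estimates against simulator ground truth (simulate mode)."""
    from scipy.stats import spearmanr

    out = {}
    main_truth: GroundTruth = truths["main"]
    tf = main_truth.to_frame()
    emp = float(np.corrcoef(tf["metabolic_trait"], tf["boldness_trait"])[0, 1]) \
        if main_truth.rho_true < 1.0 else 1.0
    out["rho_true"] = main_truth.rho_true
    out["latent_trait_correlation"] = emp

    behavior = behaviors.get("main")
    if behavior is not None and len(behavior):
        scored = bold.boldness_index(behavior)
        merged = scored.merge(
            tf[["fish_id", "boldness_trait", "metabolic_trait"]], on="fish_id"
        )
        rho_b, _ = spearmanr(merged["boldness_index"], merged["boldness_trait"])
        out["boldness_index_recovery_spearman"] = float(rho_b)
        rmr = _rmr_frame(results["main"]).merge(
            tf[["fish_id", "metabolic_trait"]], on="fish_id"
        )
        rho_m, _ = spearmanr(rmr["rmr"], rmr["metabolic_trait"])
        out["rmr_metabolic_trait_spearman"] = float(rho_m)
        day1 = _rmr_frame(results["main"])
        ok = day1["o2_consumed"] > 0
        slope = float(
            np.polyfit(np.log(day1.loc[ok, "mass_g"]), np.log(day1.loc[ok, "o2_consumed"]), 1)[0]
        )
        out["mass_exponent_estimate"] = slope
        out["mass_exponent_true"] = main_truth.mass_exponent
    return out


# ---------------------------------------------------------------------------
# entry points


def _child_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the configured study and return its report.

    Deterministic given (config, seed): repeated calls produce identical
    reports.  In simulate mode the three cohorts (main, fasting
    respirometry, fasting behavior) are generated from seeds derived
    from the master seed; in ingest mode they are read from
    ``config.paths`` (keys ``main``, ``fasting_respirometry``,
    ``fasting_behavior``; missing keys skip the matching block).
    """
    from .simulate import read_cohort

    config.validate()
    log: list[str] = []
    seeds = _child_seeds(config.seed, 6)

    tables: dict[str, CohortTable] = {}
    truths: dict[str, GroundTruth] = {}
    if config.mode == "simulate":
        tables["main"], truths["main"] = generate_cohort(config.cohort, seeds[0])
        if "fasting" in config.analyses:
            tables["fasting_respirometry"], truths["fasting_respirometry"] = (
                generate_cohort(config.fasting_respirometry, seeds[1])
            )
            tables["fasting_behavior"], truths["fasting_behavior"] = generate_cohort(
                config.fasting_behavior, seeds[2]
            )
    else:
        issues = validate_inputs(config.paths)
        fatal = [i for i in issues if i["severity"] == "error"]
        if fatal:
            first = fatal[0]
            raise ValueError(
                f"ingest validation failed: {first['file']}: {first['message']} "
                f"({len(fatal)} error(s) total)"
            )
        for key, path in config.paths.items():
            tables[key] = read_cohort(path)

    report = StudyReport(
        meta={
            "mode": config.mode,
            "seed": config.seed,
            "alpha": config.alpha,
            "n_perm": config.n_perm,
            "n_boot": config.n_boot,
            "analyses": list(config.analyses),
        },
        qc={},
        log=log,
    )

    results: dict[str, list] = {}
    behaviors: dict[str, pd.DataFrame] = {}
    main = tables.get("main")
    if main is not None:
        main_results, excluded = _metabolic_results(main)
        results["main"] = main_results
        report.qc["main_respirometry"] = {
            "n_input": len(main.respirometry),
            "n_excluded": len(excluded),
            "excluded": excluded,
        }
        if main.trajectories:
            behaviors["main"] = _behavior_frame(main, config)
            report.qc["main_behavior"] = {
                "n_input": len(main.trajectories),
                "n_excluded": 0,
                "excluded": [],
            }
        if "repeatability" in config.analyses:
            report.repeatability = _repeatability_block(
                main, main_results, config, seeds[3], log
            )
        report.mass_correlations = _mass_correlation_block(main, main_results, config, log)
        report.anova_rmr = _anova_block(main, main_results, config, seeds[4])
        if "pols_correlations" in config.analyses and "main" in behaviors:
            report.correlation_screen = _correlation_screen_block(
                behaviors["main"], main_results, config, log
            )

    if (
        "fasting" in config.analyses
        and "fasting_respirometry" in tables
        and "fasting_behavior" in tables
    ):
        report.fasting = _fasting_block(
            tables["fasting_respirometry"], tables["fasting_behavior"],
            config, seeds[5], log,
        )

    if config.mode == "simulate" and "main" in truths:
        report.recovery = _recovery_block(truths, tables, behaviors, results)

    return report


# ---------------------------------------------------------------------------
# input validation (ingest mode)


def validate_inputs(paths: dict) -> list[dict]:
    """Schema and cross-reference checks on cohort directories.

    Returns a list of issue dicts (file, message, severity); an empty
    list means every check passed.  Non-fatal issues (e.g. a respirometry
    row with a missing blank reading, which QC will exclude) are
    severity ``warning``.
    """
    from .respirometry import RESPIROMETRY_COLUMNS
    from .trajectory import TRAJECTORY_COLUMNS

    issues: list[dict] = []

    def err(file, message, severity="error"):
        issues.append({"file": str(file), "message": message, "severity": severity})

    for key, path in paths.items():
        root = Path(path)
        if not root.is_dir():
            err(root, "cohort directory does not exist")
            continue
        meta_path = root / "metadata.csv"
        resp_path = root / "respirometry.csv"
        if not meta_path.exists():
            err(meta_path, "missing metadata.csv")
            continue
        meta = pd.read_csv(meta_path)
        needed = ["fish_id", "strain", "sex", "feed_state", "mass_g"]
        missing = [c for c in needed if c not in meta.columns]
        if missing:
            err(meta_path, f"missing columns {missing}")
            continue
        meta_ids = set(meta["fish_id"].astype(str))
        if meta["fish_id"].duplicated().any():
            dups = sorted(meta.loc[meta["fish_id"].duplicated(), "fish_id"].astype(str))
            err(meta_path, f"duplicate fish_id(s): {dups}")

        if resp_path.exists():
            rdf = pd.read_csv(resp_path)
            missing = [c for c in RESPIROMETRY_COLUMNS if c not in rdf.columns]
            if missing:
                err(resp_path, f"missing columns {missing}")
            else:
                dup = rdf.duplicated(subset=["fish_id", "session_day"])
                if dup.any():
                    pairs = rdf.loc[dup, ["fish_id", "session_day"]].to_records(index=False)
                    err(resp_path, f"duplicate (fish_id, session_day): {list(pairs)}")
                for col in ("o2_blank_t1", "o2_blank_t2", "o2_fish_t1", "o2_fish_t2"):
                    bad = rdf[rdf[col].isna()]
                    for fid in bad["fish_id"].astype(str):
                        err(resp_path, f"fish {fid}: missing reading in column {col}",
                            severity="warning")
                unknown = set(rdf["fish_id"].astype(str)) - meta_ids
                if unknown:
                    err(resp_path,
                        f"fish in respirometry but not metadata: {sorted(unknown)}")

        tdir = root / "trajectories"
        if tdir.is_dir():
            traj_ids = {p.stem for p in tdir.glob("*.csv")}
            unknown = traj_ids - meta_ids
            if unknown:
                err(tdir, f"trajectories without metadata: {sorted(unknown)}")
            orphan = meta_ids - traj_ids
            if orphan and traj_ids:
                err(tdir, f"metadata fish without trajectories: {sorted(orphan)}",
                    severity="warning")
            for p in sorted(tdir.glob("*.csv")):
                header = pd.read_csv(p, nrows=0).columns
                missing = [c for c in TRAJECTORY_COLUMNS if c not in header]
                if missing:
                    err(p, f"missing columns {missing}")
    return issues
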
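"""End-to-end scenario runner: simulate, fit, filter, select, aggregate.

A scenario run walks the full Monte-Carlo grid — for every repetition,
sample size and follow-up level it fits the requested families, applies
the plausibility filters, selects a best fit per criterion (the
generating family is always also carried as the ``true_family``
criterion), computes the estimands, and finally aggregates everything
into a per-grouping performance table.

Results are deterministic given the master seed: each repetition uses
its own seed substream, so the outcome is independent of execution order
and of the number of worker processes, and an interrupted run can be
resumed by recomputing only the missing repetitions.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import plausibility as plaus
from .estimands import (
    ESTIMAND_NAMES,
    compute_estimands,
    interval_estimands,
    population_truth,
)
from .families import FAMILY_ORDER, get_family
from .fitting import fit_mle
from .plausibility import assess_plausibility, select_best
from .simulate import (
    Population,
    ScenarioConfig,
    apply_administrative_censoring,
    censor_time_for_proportion,
    draw_sample,
    generate_population,
    repetition_rng,
)

__all__ = ["RunManifest", "RunResult", "run_scenario", "summarize"]

logger = logging.getLogger("parsurvsim")

_FLOAT_FMT = None  # pandas shortest-repr: exact round-trip, needed for resume identity
_FIT_COLS = [
    "rep", "n_obs", "pe", "family", "converged", "plausible", "reasons",
    "loglik", "k", "n", "n_events", "aic", "bic", "aicc", "bicc", "params",
]
_SEL_COLS = [
    "rep", "n_obs", "pe", "criterion", "chosen_family", "was_true_family",
    "n_excluded",
]
_EST_COLS = ["rep", "n_obs", "pe", "criterion", "estimand", "point", "lo", "hi"]


@dataclass
class RunManifest:
    """Bookkeeping for one scenario run."""

    scenario: str
    seed: int
    n_sim: int
    n_datasets: int
    n_fits: int
    n_nonconverged: int
    n_implausible: int
    implausible_by_reason: dict
    n_no_selection: int
    wall_time_s: float
    config: dict
    output_files: dict

    def check_arithmetic(self, n_families: int):
        cfg = ScenarioConfig(**self.config)
        assert self.n_datasets == cfg.n_datasets
        assert self.n_fits == self.n_datasets * n_families

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class RunResult:
    manifest: RunManifest
    fits: pd.DataFrame
    selections: pd.DataFrame
    estimands: pd.DataFrame
    performance: pd.DataFrame
    truth: dict


def _fit_rng(config, rep, i_obs, i_pe, i_fam):
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(2, rep, i_obs, i_pe, i_fam))
    )


def _ci_rng(config, rep, i_obs, i_pe, i_fam):
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(3, rep, i_obs, i_pe, i_fam))
    )


def _process_repetition(
    config: ScenarioConfig,
    pop: Population,
    rep: int,
    families,
    criteria,
    th_pop: float,
    pop_max_event_time: float,
    with_estimands: bool,
    estimand_cis: bool,
):
    """All fits, selections and estimands for one repetition."""
    fit_rows, sel_rows, est_rows = [], [], []
    rng = repetition_rng(config, rep)
    fam_objs = [get_family(f) for f in families]
    for i_obs, n_obs in enumerate(config.n_obs_levels):
        idx = draw_sample(pop, n_obs, rng)
        enr = pop.enroll_times[idx]
        ev = pop.event_times[idx]
        for i_pe, pe in enumerate(config.pe_levels):
            c = censor_time_for_proportion(enr, ev, pe)
            ds = apply_administrative_censoring(
                enr, ev, c, rep=rep, n_obs=n_obs, pe=pe
            )
            models, verdicts = [], []
            for i_fam, fam in enumerate(fam_objs):
                model = fit_mle(fam, ds.times, ds.events)
                verdict = assess_plausibility(
                    model,
                    ds.times,
                    ds.events,
                    pop_max_event_time,
                    b_ci=config.b_ci,
                    rng=_fit_rng(config, rep, i_obs, i_pe, i_fam),
                )
                models.append(model)
                verdicts.append(verdict)
                row = model.to_row()
                row.update(
                    rep=rep,
                    n_obs=n_obs,
                    pe=pe,
                    plausible=verdict.plausible,
                    reasons=";".join(verdict.reasons),
                )
                fit_rows.append(row)
            for criterion in criteria:
                sel = select_best(models, verdicts, criterion)
                sel_rows.append(
                    {
                        "rep": rep,
                        "n_obs": n_obs,
                        "pe": pe,
                        "criterion": criterion,
                        "chosen_family": sel.chosen_family or "",
                        "was_true_family": sel.was_true_family,
                        "n_excluded": sel.n_excluded,
                    }
                )
                if not with_estimands:
                    continue
                if sel.chosen_index is None:
                    est_rows.extend(
                        {
                            "rep": rep, "n_obs": n_obs, "pe": pe,
                            "criterion": criterion, "estimand": name,
                            "point": np.nan, "lo": np.nan, "hi": np.nan,
                        }
                        for name in ESTIMAND_NAMES
                    )
                    continue
                chosen = models[sel.chosen_index]
                if estimand_cis:
                    est = interval_estimands(
                        chosen,
                        th_pop,
                        b=config.b_ci,
                        rng=_ci_rng(
                            config, rep, i_obs, i_pe, sel.chosen_index
                        ),
                    )
                    if est.ci_failure:
                        # visible exclusion downstream: point kept, CI blank
                        est.lo = {}
                        est.hi = {}
                else:
                    est = compute_estimands(chosen, th_pop)
                est_rows.extend(
                    est.rows(
                        rep=rep, n_obs=n_obs, pe=pe, criterion=criterion
                    )
                )
    return fit_rows, sel_rows, est_rows


def _write_chunk(path: Path, df: pd.DataFrame, header: bool):
    df.to_csv(
        path,
        mode="a",
        header=header,
        index=False,
        float_format=_FLOAT_FMT,
    )


def _completed_reps(out_dir: Path) -> set:
    sentinel = out_dir / "completed_reps.txt"
    if not sentinel.exists():
        return set()
    return {int(line) for line in sentinel.read_text().split() if line.strip()}


def run_scenario(
    config: ScenarioConfig,
    criteria=("aic", "bic", "true_family"),
    out_dir=None,
    families=FAMILY_ORDER,
    with_estimands: bool = True,
    estimand_cis: bool = False,
    resume: bool = False,
    workers: int = 1,
    scenario: str = "custom",
) -> RunResult:
    """Run one scenario end to end.

    Parameters
    ----------
    config : ScenarioConfig
        Scenario settings (rates, grid, seed, CI draws, truth source).
    criteria : sequence of str
        Selection criteria to evaluate; ``true_family`` is added if
        missing so correctly-specified performance is always available.
    out_dir : path, optional
        If given, per-repetition rows are journaled there (supporting
        ``resume``) and final tables are written as delimited text.
    families : sequence of str
        Families to fit (default: all six).
    with_estimands : bool
        Compute estimand values for the selected models.
    estimand_cis : bool
        Also compute percentile CIs (B = ``config.b_ci`` draws each).
    resume : bool
        Recompute only repetitions missing from ``out_dir``.
    workers : int
        Worker processes; results are identical for any value.
    """
    t_start = time.time()
    criteria = list(criteria)
    if "true_family" not in criteria:
        criteria.append("true_family")
    for crit in criteria:
        if crit not in plaus.CRITERIA:
            raise ValueError(f"unknown criterion {crit!r}")
    families = [get_family(f).name for f in families]

    out_path = Path(out_dir) if out_dir is not None else None
    done: set = set()
    prior = {}
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        if not _probe_writable(out_path):
            raise OSError(f"output directory {out_path} is not writable")
        if resume:
            done = _completed_reps(out_path)
            prior = _load_journal(out_path, done)
        else:
            for name in (
                "fits.csv", "selections.csv", "estimands.csv",
                "completed_reps.txt",
            ):
                (out_path / name).unlink(missing_ok=True)

    pop = generate_population(config)
    truth = population_truth(config, pop, source=config.truth_source)
    th_pop = truth.th_pop
    pop_max = pop.max_event_time

    todo = [r for r in range(config.n_sim) if r not in done]
    logger.info(
        "scenario %s: %d repetitions to run (%d already done)",
        scenario, len(todo), len(done),
    )

    args = (
        config, pop, families, criteria, th_pop, pop_max,
        with_estimands, estimand_cis,
    )
    chunks = _run_reps(todo, args, workers)

    all_fits = list(prior.get("fits", []))
    all_sels = list(prior.get("selections", []))
    all_ests = list(prior.get("estimands", []))
    for rep, (fit_rows, sel_rows, est_rows) in chunks:
        fdf = pd.DataFrame(fit_rows)[_FIT_COLS]
        sdf = pd.DataFrame(sel_rows)[_SEL_COLS]
        edf = (
            pd.DataFrame(est_rows)[_EST_COLS]
            if est_rows
            else pd.DataFrame(columns=_EST_COLS)
        )
        if out_path is not None:
            _write_chunk(out_path / "fits.csv", fdf, not (out_path / "fits.csv").exists())
            _write_chunk(out_path / "selections.csv", sdf, not (out_path / "selections.csv").exists())
            if with_estimands:
                _write_chunk(out_path / "estimands.csv", edf, not (out_path / "estimands.csv").exists())
            with open(out_path / "completed_reps.txt", "a") as fh:
                fh.write(f"{rep}\n")
        all_fits.append(fdf)
        all_sels.append(sdf)
        all_ests.append(edf)
        if rep % 50 == 0:
            logger.info("repetition %d done", rep)

    fits = _canonical(pd.concat(all_fits, ignore_index=True), ["rep", "n_obs", "pe"])
    sels = _canonical(pd.concat(all_sels, ignore_index=True), ["rep", "n_obs", "pe", "criterion"])
    ests = (
        _canonical(pd.concat(all_ests, ignore_index=True), ["rep", "n_obs", "pe", "criterion"])
        if with_estimands
        else pd.DataFrame(columns=_EST_COLS)
    )

    from .performance import performance_table

    perf = (
        performance_table(ests, sels, truth.as_dict())
        if with_estimands and len(ests)
        else pd.DataFrame()
    )

    n_fits = len(fits)
    nonconv = int((~fits["converged"].astype(bool)).sum())
    implaus_mask = ~fits["plausible"].astype(bool)
    by_reason: dict = {}
    for rs in fits.loc[implaus_mask, "reasons"]:
        for r in str(rs).split(";"):
            if r:
                by_reason[r] = by_reason.get(r, 0) + 1
    n_no_sel = int((sels["chosen_family"] == "").sum())

    manifest = RunManifest(
        scenario=str(scenario),
        seed=config.seed,
        n_sim=config.n_sim,
        n_datasets=config.n_datasets,
        n_fits=n_fits,
        n_nonconverged=nonconv,
        n_implausible=int(implaus_mask.sum()),
        implausible_by_reason=by_reason,
        n_no_selection=n_no_sel,
        wall_time_s=round(time.time() - t_start, 2),
        config=asdict(config),
        output_files={},
    )

    if out_path is not None:
        # canonical, sorted final tables (byte-identical across resumes)
        fits.to_csv(out_path / "fits.csv", index=False, float_format=_FLOAT_FMT)
        sels.to_csv(out_path / "selections.csv", index=False, float_format=_FLOAT_FMT)
        if with_estimands:
            ests.to_csv(out_path / "estimands.csv", index=False, float_format=_FLOAT_FMT)
            perf.to_csv(out_path / "performance.csv", index=False, float_format=_FLOAT_FMT)
        config.to_yaml(out_path / "config.yaml")
        manifest.output_files = {
            "fits": str(out_path / "fits.csv"),
            "selections": str(out_path / "selections.csv"),
            "estimands": str(out_path / "estimands.csv"),
            "performance": str(out_path / "performance.csv"),
        }
        manifest.to_yaml(out_path / "manifest.yaml")

    return RunResult(
        manifest=manifest,
        fits=fits,
        selections=sels,
        estimands=ests,
        performance=perf,
        truth=truth.as_dict(),
    )


def _probe_writable(path: Path) -> bool:
    try:
        probe = path / ".write_probe"
        probe.touch()
        probe.unlink()
        return True
    except OSError:
        return False


def _canonical(df: pd.DataFrame, keys) -> pd.DataFrame:
    if not len(df):
        return df
    return df.sort_values(keys, kind="mergesort").reset_index(drop=True)


def _load_journal(out_path: Path, done: set) -> dict:
    """Rows journaled by completed repetitions of a previous run."""
    out = {}
    for key, name in (
        ("fits", "fits.csv"),
        ("selections", "selections.csv"),
        ("estimands", "estimands.csv"),
    ):
        p = out_path / name
        if p.exists():
            # round_trip parsing: journaled floats must reload bit-exactly
            df = pd.read_csv(p, float_precision="round_trip")
            df = df[df["rep"].isin(done)]
            out[key] = [df]
            # rewrite the journal without rows from interrupted reps
            df.to_csv(p, index=False, float_format=_FLOAT_FMT)
    return out


def _run_reps(todo, args, workers):
    """Yield (rep, chunk) in repetition order, optionally in parallel."""
    if workers <= 1:
        for rep in todo:
            yield rep, _process_repetition(args[0], args[1], rep, *args[2:])
        return
    import concurrent.futures as cf

    with cf.ProcessPoolExecutor(max_workers=workers) as pool:
        futures = {
            rep: pool.submit(_process_repetition, args[0], args[1], rep, *args[2:])
            for rep in todo
        }
        for rep in todo:  # collect in order for deterministic journals
            yield rep, futures[rep].result()


def _run_scenario_label(out_path: Path) -> str:
    manifest = out_path / "manifest.yaml"
    if manifest.exists():
        with open(manifest) as fh:
            return str(yaml.safe_load(fh).get("scenario", out_path.name))
    return out_path.name


def summarize(out_dir, criterion=None, estimand=None, n_obs=None, pe=None):
    """Filtered slice of one run's performance table (or of several runs
    concatenated, for cross-scenario comparison, when ``out_dir`` is a
    list of run directories).

    Raises a descriptive error naming the missing stage if a run has not
    produced a performance table; warns (and returns an empty frame) if a
    filter matches nothing.
    """
    import warnings

    if isinstance(out_dir, (list, tuple)):
        parts = []
        for d in out_dir:
            t = summarize(d)
            t.insert(0, "scenario", _run_scenario_label(Path(d)))
            parts.append(t)
        table = pd.concat(parts, ignore_index=True)
    else:
        out_path = Path(out_dir)
        perf_path = out_path / "performance.csv"
        if not out_path.exists():
            raise FileNotFoundError(
                f"run directory {out_path} does not exist"
            )
        if not perf_path.exists():
            raise FileNotFoundError(
                f"{perf_path} missing: the aggregation stage has not run "
                "(run the scenario with estimands enabled first)"
            )
        table = pd.read_csv(perf_path)
    for col, val in (
        ("criterion", criterion),
        ("estimand", estimand),
        ("n_obs", n_obs),
        ("pe", pe),
    ):
        if val is None:
            continue
        sub = table[table[col] == val]
        if not len(sub):
            warnings.warn(
                f"filter {col}={val!r} matched no rows", stacklevel=2
            )
        table = sub
    return table.reset_index(drop=True)
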
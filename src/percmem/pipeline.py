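"""End-to-end pipeline: simulate -> triplets -> reverse correlation -> fits.

``run_pipeline`` regenerates every artifact from the run config alone:

* ``trials.csv`` — the simulated trial log;
* ``estimates_individual.csv`` / ``estimates_group.csv`` — per-segment
  reverse-correlation means with 97% bootstrap CIs for both selection sets;
* ``comparison_linear_additive.csv`` — LOO table, linear vs additive model
  on the prime-perception selection;
* ``comparison_dual.csv`` — LOO table for the three dual-condition variants;
* ``scaling_contrast.csv`` — per-participant posterior probability that the
  memory scaling weight is below the perception one (identical model);
* ``draws.csv`` — posterior draws, columnar (model, parameter, chain, draw,
  value);
* ``run_log.json`` — package/library versions, seeds and stage inventory.

Any stage failure aborts with the stage name attached.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import RunConfig, estimates_frame, write_trial_log
from .models import (
    compare_models,
    dual_observations,
    fit_additive,
    fit_dual,
    fit_hierarchical_linear,
    loo_elpd,
    segment_observations,
    weight_contrast_fraction,
)
from .observer import simulate_session
from .sampler import MCMCConfig
from .schedules import segment_onset_times
from .splines import build_basis
from .triplets import (
    BootstrapConfig,
    NoQualifyingTrialsError,
    bootstrap_group,
    bootstrap_individual,
    build_triplets,
)

__all__ = ["run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    return wrap


def _draws_frame(model: str, draws: dict[str, np.ndarray]) -> pd.DataFrame:
    frames = []
    for name, arr in draws.items():
        if arr.ndim == 2:
            arr = arr[:, :, None]
            labels = [name]
        else:
            labels = [f"{name}[{j + 1}]" for j in range(arr.shape[2])]
        n_chain, n_draw, k = arr.shape
        chain_idx = np.repeat(np.arange(n_chain), n_draw)
        draw_idx = np.tile(np.arange(n_draw), n_chain)
        for j, label in enumerate(labels):
            frames.append(
                pd.DataFrame(
                    {
                        "model": model,
                        "parameter": label,
                        "chain": chain_idx,
                        "draw": draw_idx,
                        "value": arr[:, :, j].ravel(),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full analysis and write all artifacts to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schedule = config.schedule()
    onsets = segment_onset_times(schedule)
    written: list[str] = []

    # --- simulate ---------------------------------------------------------
    def simulate():
        seeds = np.random.SeedSequence(config.seed_simulation).spawn(
            config.n_participants
        )
        return {
            f"obs{j + 1:02d}": simulate_session(
                config.observer,
                schedule,
                config.n_primes,
                np.random.default_rng(seeds[j]),
                participant=f"obs{j + 1:02d}",
            )
            for j in range(config.n_participants)
        }

    sessions = _stage("simulate")(simulate)
    _stage("simulate")(write_trial_log, sessions, out / "trials.csv")
    written.append("trials.csv")

    # --- triplets + reverse correlation -----------------------------------
    def revcorr():
        triplets = {p: build_triplets(s) for p, s in sessions.items()}
        boot = BootstrapConfig(
            n_iterations=config.bootstrap_iterations,
            interval_mass=config.interval_mass,
            seed=config.seed_bootstrap,
        )
        individual, group = {}, {}
        for selection in ("prime_changed", "memory_changed"):
            for p, tr in triplets.items():
                try:
                    individual[f"{p}:{selection}"] = bootstrap_individual(
                        tr, selection, boot
                    )
                except NoQualifyingTrialsError:
                    continue
            group[f"group:{selection}"] = bootstrap_group(triplets, selection, boot)
        return triplets, individual, group

    triplets, individual, group = _stage("revcorr")(revcorr)

    for name, block in [
        ("estimates_individual.csv", individual),
        ("estimates_group.csv", group),
    ]:
        frames = [
            estimates_frame({key.split(":")[0]: est}, onsets)
            for key, est in block.items()
        ]
        pd.concat(frames, ignore_index=True).to_csv(
            out / name, index=False, float_format="%.6f"
        )
        written.append(name)

    # --- model fits --------------------------------------------------------
    mcmc = MCMCConfig(
        n_walkers=config.mcmc_walkers,
        n_warmup=config.mcmc_warmup,
        n_steps=config.mcmc_steps,
        thin=config.mcmc_thin,
        seed=config.seed_mcmc,
    )
    basis = build_basis(schedule.n_segments)

    def fits():
        perception = segment_observations(triplets, "prime_changed")
        linear = fit_hierarchical_linear(perception, mcmc)
        additive = fit_additive(perception, basis, mcmc)
        dual_df = dual_observations(triplets)
        duals = {v: fit_dual(dual_df, basis, v, mcmc) for v in
                 ("independent", "correlated", "identical")}
        return linear, additive, duals

    linear, additive, duals = _stage("fit")(fits)

    def comparisons():
        single = compare_models(
            {"linear": loo_elpd(linear), "additive": loo_elpd(additive)}
        )
        dual = compare_models({k: loo_elpd(v) for k, v in duals.items()})
        contrast = weight_contrast_fraction(duals["identical"])
        return single, dual, contrast

    single_cmp, dual_cmp, contrast = _stage("compare")(comparisons)
    single_cmp.to_csv(out / "comparison_linear_additive.csv", float_format="%.6f")
    dual_cmp.to_csv(out / "comparison_dual.csv", float_format="%.6f")
    pd.DataFrame(
        {"participant": list(contrast), "p_memory_below_perception": list(contrast.values())}
    ).to_csv(out / "scaling_contrast.csv", index=False, float_format="%.6f")
    written += [
        "comparison_linear_additive.csv",
        "comparison_dual.csv",
        "scaling_contrast.csv",
    ]

    frames = [
        _draws_frame("hierarchical_linear", linear.draws),
        _draws_frame("additive", additive.draws),
    ] + [_draws_frame(f"dual_{k}", v.draws) for k, v in duals.items()]
    pd.concat(frames, ignore_index=True).to_csv(
        out / "draws.csv", index=False, float_format="%.6g"
    )
    written.append("draws.csv")

    # --- run log -----------------------------------------------------------
    import arviz
    import emcee
    import scipy

    log = {
        "percmem": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "emcee": emcee.__version__,
        "arviz": arviz.__version__,
        "seeds": {
            "simulation": config.seed_simulation,
            "bootstrap": config.seed_bootstrap,
            "mcmc": config.seed_mcmc,
        },
        "schedule": config.schedule_variant,
        "n_participants": config.n_participants,
        "n_primes": config.n_primes,
        "max_rhat": {
            "linear": linear.max_rhat,
            "additive": additive.max_rhat,
            **{f"dual_{k}": v.max_rhat for k, v in duals.items()},
        },
        "files": written + ["run_log.json"],
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return out
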
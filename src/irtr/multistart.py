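"""Multistart driver: repeated local optimization from sampled start points.

Failed runs are data, not errors: they contribute their gradient evaluations
to the totals and count as unsuccessful in the success count.  Outputs are
start-index ordered and fully determined by the configuration (including the
seed), so re-running a configuration reproduces every number exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .diagnostics import MultistartResult
from .objective import SearchDomain
from .optimizer import OptimizerOptions, minimize
from .problems import (
    ConversionModelFixture,
    conversion_model,
    make_nls,
    rosenbrock_problem,
    sample_startpoints,
)

__all__ = ["RunConfig", "run_multistart", "build_problem"]

FIXTURES = ("nls", "conversion", "rosenbrock")


@dataclass
class RunConfig:
    """Flat configuration of a multistart study.

    ``problem`` is a fixture name (``nls``, ``conversion``, ``rosenbrock``)
    or a path to a serialized conversion fixture directory;
    ``problem_params`` are forwarded to the fixture generator.
    """

    problem: str = "nls"
    problem_params: dict = field(default_factory=dict)
    scheme: str = "GN"
    subspace: str = "2D"
    max_reflections: Optional[int] = None
    n_starts: int = 100
    tau: Sequence[float] = (2.0,)
    seed: int = 0
    step_tol: float = 1e-6
    max_iter: int = 10**5
    delta_init: float = 1.0
    scheme_options: dict = field(default_factory=dict)
    output_dir: Optional[str] = None
    save_traces: bool = False

    def __post_init__(self) -> None:
        self.tau = tuple(float(t) for t in np.atleast_1d(self.tau))
        if any(t <= 0 for t in self.tau):
            raise ValueError("tau thresholds must be positive")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def optimizer_options(self) -> OptimizerOptions:
        return OptimizerOptions(
            scheme=self.scheme,
            subspace=self.subspace,
            max_reflections=self.max_reflections,
            step_tol=self.step_tol,
            max_iter=self.max_iter,
            delta_init=self.delta_init,
            scheme_options=dict(self.scheme_options),
            record_theta=False,
        )


def build_problem(config: RunConfig):
    """Resolve the configured problem to ``(objective, domain)``."""
    name = config.problem
    params = dict(config.problem_params)
    if name == "nls":
        params.setdefault("n_par", 5)
        params.setdefault("n_res", 12)
        params.setdefault("seed", config.seed)
        prob = make_nls(**params)
        return prob.objective, prob.domain
    if name == "conversion":
        params.setdefault("seed", config.seed)
        fix = conversion_model(**params)
        return fix.objective, fix.domain
    if name == "rosenbrock":
        objective, domain, _ = rosenbrock_problem(**params)
        return objective, domain
    path = Path(name)
    if path.is_dir() and (path / "fixture.yaml").exists():
        fix = ConversionModelFixture.load(path)
        return fix.objective, fix.domain
    raise ValueError(
        f"unknown problem {name!r}: expected one of {FIXTURES} or a fixture "
        "directory"
    )


def run_multistart(config: RunConfig) -> MultistartResult:
    """Execute the configured multistart study; optionally write outputs.

    When ``config.output_dir`` is set, writes ``metrics.csv`` (one row per
    consistency threshold tau), ``waterfall.csv`` (sorted final values),
    ``summary.json`` (configuration and aggregate outcome), and — with
    ``save_traces`` — per-run trace CSVs plus a combined HDF5 container.
    """
    objective, domain = build_problem(config)
    starts = sample_startpoints(domain, config.n_starts, seed=config.seed)
    options = config.optimizer_options()

    finals = np.empty(config.n_starts)
    iters = np.empty(config.n_starts, dtype=int)
    statuses: list[str] = []
    traces = []
    results = []
    for i in range(config.n_starts):
        res = minimize(objective, starts[i], domain, options)
        finals[i] = res.fval if np.isfinite(res.fval) else np.nan
        iters[i] = res.n_grad
        statuses.append(res.status)
        traces.append(res.trace)
        results.append(res)

    ms = MultistartResult(
        final_values=finals,
        n_iterations=iters,
        statuses=statuses,
        start_points=starts,
        tau=config.tau[0],
        traces=traces,
    )

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics = pd.DataFrame(
            [
                {
                    "scheme": config.scheme,
                    "subspace": config.subspace,
                    **ms.metrics(tau=t),
                }
                for t in config.tau
            ]
        )
        metrics.to_csv(out / "metrics.csv", index=False)
        pd.DataFrame(
            {"rank": np.arange(1, config.n_starts + 1), "fval": ms.waterfall()}
        ).to_csv(out / "waterfall.csv", index=False)
        summary = {
            "config": _jsonable(asdict(config)),
            "n_runs": int(config.n_starts),
            "n_grad_total": ms.n_grad_total,
            "statuses": {s: statuses.count(s) for s in set(statuses)},
            "best_fval": float(np.nanmin(finals)),
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        if config.save_traces:
            trace_dir = out / "traces"
            trace_dir.mkdir(exist_ok=True)
            for i, res in enumerate(results):
                res.trace_to_csv(trace_dir / f"run_{i:04d}.csv")
                res.trace_to_hdf5(out / "traces.h5", key=f"run_{i:04d}")
    return ms


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
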
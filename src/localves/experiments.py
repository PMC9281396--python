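"""Declarative experiment driver: benchmark presets, suites, aggregation.

A suite is one run configuration replicated over independent seeds
(the model-potential benchmarks use 20 replicas at full scale).  Per
snapshot of the averaged bias the driver computes the RMS-error metric
against the quadrature reference FES and/or the free energy difference
between two configured regions, then aggregates the per-run series into a
mean and standard error.

Reduced-scale presets (``*_quick``) ship alongside the full-scale ones so
the whole pipeline runs in minutes; the scale factors (steps, replicas)
are explicit configuration fields, never silent.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .basis import build_basis, tensor_basis
from .dynamics import DynamicsConfig
from .engine import (
    Adam,
    AveragedSGD,
    BiasState,
    VESConfig,
    VESResult,
    run_ves,
    uniform_target,
    well_tempered_target,
)
from .fes import (
    MetricConfig,
    fes_from_bias,
    free_energy_difference,
    halfspace,
    rms_error,
)
from .grid import FESGrid, write_grid, read_grid  # noqa: F401  (re-export)
from .potentials import get_potential, reference_fes

__all__ = [
    "PRESETS",
    "ExperimentSuite",
    "AggregateSeries",
    "SuiteResult",
    "load_suite",
    "suite_from_preset",
    "run_suite",
    "aggregate",
    "write_grid",
    "read_grid",
]


# --------------------------------------------------------------------------
# presets: the printed benchmark protocols

def _double_well(basis_kind: str, **overrides) -> dict:
    mu = {"legendre": 0.1, "chebyshev": 0.1}.get(basis_kind, 0.5)
    cfg = {
        "name": f"double_well_{basis_kind}",
        "potential": "double_well",
        "temperature": 0.5,
        "dt": 0.005,
        "friction": 10.0,
        "basis": [{"kind": basis_kind, "interval": [-3.0, 3.0], "size": 22,
                   "order": 8}],
        "target": {"kind": "uniform"},
        "optimizer": {"kind": "averaged_sgd", "mu": mu},
        "stride": 500,
        "n_steps": 5_000_000,
        "fes_stride": 50_000,
        "n_walkers": 1,
        "n_runs": 20,
        "seed": 1,
        "start": "global_minimum",
        "metrics": {"rms_error": {"nu": 8.0, "shift": 4.0},
                    "delta_f": {"dim": 0, "split": 0.0}},
        "reference": {"bins": 1000},
    }
    cfg.update(overrides)
    return cfg


def _wolfe_quapp(basis_kind: str, **overrides) -> dict:
    cfg = {
        "name": f"wolfe_quapp_{basis_kind}",
        "potential": "wolfe_quapp",
        "temperature": 1.0,
        "dt": 0.005,
        "friction": 10.0,
        "basis": [
            {"kind": basis_kind, "interval": [-3.0, 3.0], "size": 22,
             "order": 8},
            {"kind": basis_kind, "interval": [-3.0, 3.0], "size": 22,
             "order": 8},
        ],
        "target": {"kind": "uniform", "bins": 301},
        "optimizer": {"kind": "averaged_sgd", "mu": 0.5},
        "stride": 500,
        "n_steps": 5_000_000,
        "fes_stride": 50_000,
        "n_walkers": 1,
        "n_runs": 20,
        "seed": 1,
        "start": "global_minimum",
        "metrics": {"delta_f": {"dim": 1, "split": 0.0}},
        "reference": {"bins": 301},
    }
    cfg.update(overrides)
    return cfg


def _wolfe_quapp_rotated(basis_kind: str, **overrides) -> dict:
    cfg = {
        "name": f"wolfe_quapp_rotated_{basis_kind}",
        "potential": "wolfe_quapp_rotated",
        "temperature": 1.0,
        "dt": 0.005,
        "friction": 10.0,
        "basis": [{"kind": basis_kind, "interval": [-3.0, 3.0], "size": 22,
                   "order": 8}],
        "target": {"kind": "uniform"},
        "optimizer": {"kind": "adam", "eta": 0.005},
        "stride": 500,
        "n_steps": 5_000_000,
        "fes_stride": 50_000,
        "n_walkers": 1,
        "n_runs": 20,
        "seed": 1,
        "start": "global_minimum",
        "metrics": {"delta_f": {"dim": 0, "split": 0.0}},
        "reference": {"bins": 1000, "marginalize": [1]},
    }
    cfg.update(overrides)
    return cfg


PRESETS: dict[str, dict] = {}
for _kind in ("wavelet", "gaussian", "bspline", "legendre"):
    PRESETS[f"double_well_{_kind}"] = _double_well(_kind)
    PRESETS[f"double_well_{_kind}_quick"] = _double_well(
        _kind, name=f"double_well_{_kind}_quick",
        n_steps=500_000, n_runs=5, fes_stride=50_000,
    )
for _kind in ("wavelet", "legendre"):
    PRESETS[f"wolfe_quapp_{_kind}"] = _wolfe_quapp(_kind)
    PRESETS[f"wolfe_quapp_rotated_{_kind}"] = _wolfe_quapp_rotated(_kind)
PRESETS["wolfe_quapp_wavelet_quick"] = _wolfe_quapp(
    "wavelet", name="wolfe_quapp_wavelet_quick",
    n_steps=100_000, n_runs=2, fes_stride=25_000,
)


# --------------------------------------------------------------------------
# suite construction

@dataclass
class ExperimentSuite:
    """One run configuration replicated over independent seeds."""

    config: dict
    outdir: Path | None = None

    def __post_init__(self):
        self.config = copy.deepcopy(self.config)
        if self.outdir is not None:
            self.outdir = Path(self.outdir)

    @property
    def n_runs(self) -> int:
        return int(self.config.get("n_runs", 1))

    @property
    def seeds(self) -> list[int]:
        base = int(self.config.get("seed", 0))
        return [base + i for i in range(self.n_runs)]

    def describe(self) -> str:
        return yaml.safe_dump(self.config, sort_keys=False)


def suite_from_preset(name: str, outdir=None, **overrides) -> ExperimentSuite:
    try:
        cfg = copy.deepcopy(PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    cfg.update(overrides)
    return ExperimentSuite(config=cfg, outdir=outdir)


def load_suite(path, outdir=None) -> ExperimentSuite:
    """Load a suite from a YAML document (same schema as the presets)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "preset" in cfg:
        base = copy.deepcopy(PRESETS[cfg.pop("preset")])
        base.update(cfg)
        cfg = base
    return ExperimentSuite(config=cfg, outdir=outdir)


def _build_run_config(cfg: dict, seed: int) -> VESConfig:
    potential = get_potential(cfg["potential"])
    blocks = cfg["basis"]
    bases = [build_basis(b) for b in blocks]
    basis = bases[0] if len(bases) == 1 else tensor_basis(*bases)
    beta = 1.0 / float(cfg["temperature"])
    dyn = DynamicsConfig(
        dt=float(cfg.get("dt", 0.005)),
        friction=float(cfg.get("friction", 10.0)),
        beta=beta,
        mass=float(cfg.get("mass", 1.0)),
    )
    tgt_cfg = dict(cfg.get("target", {"kind": "uniform"}))
    bins = tgt_cfg.pop("bins", 1000 if basis.dim == 1 else 301)
    if tgt_cfg.get("kind", "uniform") == "uniform":
        target = uniform_target(basis.intervals, bins)
    else:
        target = well_tempered_target(
            basis.intervals, gamma=float(tgt_cfg["gamma"]), bins=bins,
            update_stride=int(tgt_cfg.get("update_stride", 100)),
        )
    opt_cfg = dict(cfg.get("optimizer", {"kind": "averaged_sgd"}))
    okind = opt_cfg.pop("kind", "averaged_sgd")
    if okind == "averaged_sgd":
        optimizer = AveragedSGD(mu=float(opt_cfg.get("mu", 0.5)))
    elif okind == "adam":
        optimizer = Adam(eta=float(opt_cfg.get("eta", 0.005)))
    else:
        raise ValueError(f"unknown optimizer kind {okind!r}")
    start = cfg.get("start", "global_minimum")
    start_position = None if start == "global_minimum" else np.asarray(start)
    return VESConfig(
        potential=potential,
        basis=basis,
        dynamics=dyn,
        target=target,
        optimizer=optimizer,
        n_steps=int(cfg["n_steps"]),
        stride=int(cfg.get("stride", 500)),
        fes_stride=int(cfg.get("fes_stride", 50_000)),
        n_walkers=int(cfg.get("n_walkers", 1)),
        seed=seed,
        start_position=start_position,
        record_samples=bool(cfg.get("record_samples", False)),
    )


# --------------------------------------------------------------------------
# aggregation

@dataclass
class AggregateSeries:
    """Per-iteration mean and standard error over independent runs."""

    iterations: np.ndarray
    per_run: np.ndarray          # shape (n_runs, n_snapshots)
    mean: np.ndarray = field(init=False)
    sem: np.ndarray = field(init=False)

    def __post_init__(self):
        self.iterations = np.asarray(self.iterations)
        self.per_run = np.atleast_2d(np.asarray(self.per_run, dtype=float))
        if self.per_run.shape[1] != len(self.iterations):
            raise ValueError("series and iteration axis have different length")
        self.mean = self.per_run.mean(axis=0)
        n = self.per_run.shape[0]
        if n > 1:
            self.sem = self.per_run.std(axis=0, ddof=1) / np.sqrt(n)
        else:
            self.sem = np.zeros_like(self.mean)


def aggregate(series_per_run, iterations=None) -> AggregateSeries:
    """Element-wise mean and standard error over runs on one axis."""
    arrs = [np.asarray(s, dtype=float) for s in series_per_run]
    if not arrs:
        raise ValueError("need at least one series")
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("mismatched iteration axes across runs")
    if iterations is None:
        iterations = np.arange(1, n + 1)
    return AggregateSeries(iterations=iterations, per_run=np.stack(arrs))


# --------------------------------------------------------------------------
# suite execution

@dataclass
class SuiteResult:
    suite: ExperimentSuite
    runs: list[VESResult]
    failures: list[tuple[int, str]]
    reference: FESGrid
    snapshots_iterations: np.ndarray
    rms: AggregateSeries | None
    delta_f: AggregateSeries | None
    final_fes: list[FESGrid]


def _metric_setup(cfg: dict, potential, beta):
    ref_cfg = dict(cfg.get("reference", {}))
    bins = ref_cfg.get("bins", 1000)
    marg = ref_cfg.get("marginalize", [])
    ref = reference_fes(potential, beta, grid_bins=bins, marginalize=marg)
    metrics = cfg.get("metrics", {})
    mcfg = None
    if "rms_error" in metrics:
        m = metrics["rms_error"]
        mcfg = MetricConfig(
            nu=float(m.get("nu", 8.0)),
            shift_region_threshold=float(m.get("shift", 4.0)),
        )
    regions = None
    if "delta_f" in metrics:
        m = metrics["delta_f"]
        d, split = int(m.get("dim", 0)), float(m.get("split", 0.0))
        regions = (halfspace(d, "<", split), halfspace(d, ">", split))
    return ref, mcfg, regions


def run_suite(suite: ExperimentSuite, progress=None) -> SuiteResult:
    """Execute every replica, compute metric series, aggregate, write files.

    Replica failures are recorded and the aggregate is computed over the
    completed runs (with a warning).  With an output directory set, writes
    per-run metric series, the aggregate series, final FES grids and the
    final coefficients as plain-text files.
    """
    cfg = suite.config
    beta = 1.0 / float(cfg["temperature"])
    potential = get_potential(cfg["potential"])
    ref, mcfg, regions = _metric_setup(cfg, potential, beta)

    runs: list[VESResult] = []
    failures: list[tuple[int, str]] = []
    rms_series, df_series = [], []
    final_fes = []
    snap_iters = None
    for i, seed in enumerate(suite.seeds):
        run_cfg = _build_run_config(cfg, seed)
        try:
            result = run_ves(run_cfg)
        except Exception as exc:  # noqa: BLE001 - replica isolation
            failures.append((i, f"{type(exc).__name__}: {exc}"))
            continue
        runs.append(result)
        iters = np.array([it for it, _, _ in result.snapshots])
        if snap_iters is None:
            snap_iters = iters
        rser, dser = [], []
        for _, _, alpha_bar in result.snapshots:
            b = BiasState(run_cfg.basis, alpha_bar, alpha_bar)
            fes = fes_from_bias(b, result.target, beta, grid=ref)
            if mcfg is not None:
                rser.append(rms_error(fes, ref, beta, mcfg))
            if regions is not None:
                dser.append(free_energy_difference(fes, beta, *regions))
        if mcfg is not None:
            rms_series.append(np.asarray(rser))
        if regions is not None:
            df_series.append(np.asarray(dser))
        b = BiasState(run_cfg.basis, result.bias.alpha_bar,
                      result.bias.alpha_bar)
        final_fes.append(fes_from_bias(b, result.target, beta, grid=ref))
        if progress:
            progress(i, len(suite.seeds))

    if failures and runs:
        import warnings

        warnings.warn(
            f"{len(failures)} of {suite.n_runs} replicas failed; "
            "aggregate uses completed runs only",
            RuntimeWarning,
            stacklevel=2,
        )
    rms_agg = (
        aggregate(rms_series, snap_iters) if mcfg is not None and rms_series
        else None
    )
    df_agg = (
        aggregate(df_series, snap_iters) if regions is not None and df_series
        else None
    )
    result = SuiteResult(
        suite=suite, runs=runs, failures=failures, reference=ref,
        snapshots_iterations=snap_iters if snap_iters is not None else np.array([]),
        rms=rms_agg, delta_f=df_agg, final_fes=final_fes,
    )
    if suite.outdir is not None:
        _write_outputs(result)
    return result


def _write_series(path: Path, iterations, columns: dict[str, np.ndarray]):
    with path.open("w") as fh:
        fh.write("# FIELDS iteration " + " ".join(columns) + "\n")
        for j, it in enumerate(iterations):
            row = " ".join(f"{columns[c][j]:.10g}" for c in columns)
            fh.write(f"{int(it)} {row}\n")


def _write_outputs(res: SuiteResult) -> None:
    out = res.suite.outdir
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(res.suite.describe())
    write_grid(res.reference, out / "reference_fes.dat")
    for agg, stem in ((res.rms, "rms_error"), (res.delta_f, "delta_f")):
        if agg is None:
            continue
        cols = {f"run{i}": agg.per_run[i] for i in range(agg.per_run.shape[0])}
        _write_series(out / f"{stem}_runs.dat", agg.iterations, cols)
        _write_series(
            out / f"{stem}_mean.dat", agg.iterations,
            {"mean": agg.mean, "sem": agg.sem},
        )
    for i, (fes, run) in enumerate(zip(res.final_fes, res.runs)):
        write_grid(fes, out / f"fes_run{i}.dat")
        m = run.bias.basis.size
        hist = np.array(
            [np.concatenate([[it], a, ab]) for it, a, ab in run.snapshots]
        )
        cols = (
            ["iteration"]
            + [f"alpha{j}" for j in range(m)]
            + [f"alpha_bar{j}" for j in range(m)]
        )
        np.savetxt(
            out / f"coeffs_run{i}.dat", hist,
            header=" ".join(cols), fmt="%.12g",
        )
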
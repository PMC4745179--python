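"""Orchestration of the model's computational experiments.

- network-comparison suite: the same stimulus set run through the
  no-inhibition, single-connection, and example-unit wirings, to show
  hotspot emergence on matched inputs;
- tuning-width sweep: goodness of fit of the spatial grid as the input
  channels' Gaussian tuning is broadened from the no-crosstalk regime
  (2*sigma < 15 deg) through 40, 80, 120 deg;
- multi-masker prediction: discriminability with several simultaneous
  maskers vs the single-masker baselines;
- staged coordinate-wise fitting of a network config to a target grid
  (adaptation -> feedforward weights -> per-connection lateral weights),
  with frozen input spikes so the objective is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._seeding import child_int
from .metrics import (
    DEFAULT_MASKER_GAIN,
    DEFAULT_TAU,
    DiscriminabilityGrid,
    discriminability,
    goodness_of_fit,
    masker_tokens,
    spatial_grid,
)
from .network import (
    DEFAULT_LATERAL_WEIGHT,
    Network,
    NetworkConfig,
    build_network,
    preset,
)
from .spatial import DEFAULT_AZIMUTHS, Scene, SceneSource
from .stimuli import TFGrid, make_masker, make_song

__all__ = [
    "ExperimentSpec",
    "FitResult",
    "make_stimuli",
    "run_fig2_suite",
    "run_width_sweep",
    "run_multimasker",
    "fit_to_grid",
]

SWEEP_WIDTHS = (40.0, 80.0, 120.0)  # 2*sigma, degrees


@dataclass
class ExperimentSpec:
    """Shared settings for the experiment drivers."""

    grid: TFGrid = field(default_factory=TFGrid)
    stim_seed: int = 7           # songs and frozen masker
    seed: int = 1                # simulation root seed
    azimuths: tuple = DEFAULT_AZIMUTHS
    widths: tuple = SWEEP_WIDTHS
    n_trials: int = 10
    tau: float = DEFAULT_TAU
    masker_gain: float = DEFAULT_MASKER_GAIN
    masker_refresh: bool = True
    lateral_weight: float = DEFAULT_LATERAL_WEIGHT

    def __post_init__(self):
        if any(w <= 0 for w in self.widths):
            raise ValueError("tuning widths must be positive")
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")


def make_stimuli(spec: ExperimentSpec):
    """(song1, song2, masker) on the spec's grid."""
    return (
        make_song(spec.grid, 1, spec.stim_seed),
        make_song(spec.grid, 2, spec.stim_seed),
        make_masker(spec.grid, spec.stim_seed),
    )


def _grid_for(config: NetworkConfig, spec: ExperimentSpec) -> DiscriminabilityGrid:
    song1, song2, masker = make_stimuli(spec)
    return spatial_grid(
        build_network(config), song1, song2, masker,
        azimuths=spec.azimuths, n_trials=spec.n_trials, tau=spec.tau,
        seed=spec.seed, masker_gain=spec.masker_gain,
        masker_refresh=spec.masker_refresh,
    )


def run_fig2_suite(spec: ExperimentSpec, base: NetworkConfig | None = None):
    """Spatial grids for the three canonical wirings on matched inputs.

    Returns (grids: dict name -> DiscriminabilityGrid, report: dict).
    The report quantifies hotspot emergence: masked-grid spread of each
    wiring and the gain of the (target 0, masker -90) cell over the
    no-inhibition network.
    """
    if base is None:
        base = NetworkConfig()
    grids = {}
    for name in ("no_inhibition", "fig2b", "fig2c"):
        cfg = preset(name, base, weight=spec.lateral_weight)
        grids[name] = _grid_for(cfg, spec)

    az = list(spec.azimuths)
    i_t, i_m = az.index(0.0), az.index(-90.0)
    report = {
        "masked_sd": {n: float(np.std(g.masked)) for n, g in grids.items()},
        "clean_rows_identical": bool(
            np.array_equal(grids["no_inhibition"].clean, grids["fig2b"].clean)
            and np.array_equal(grids["no_inhibition"].clean, grids["fig2c"].clean)
        ),
        "hotspot_cell": {n: float(g.masked[i_m, i_t]) for n, g in grids.items()},
        "hotspot_gain_fig2b": float(
            grids["fig2b"].masked[i_m, i_t] - grids["no_inhibition"].masked[i_m, i_t]
        ),
    }
    return grids, report


def run_width_sweep(
    spec: ExperimentSpec,
    base: NetworkConfig | None = None,
    reference_grid: DiscriminabilityGrid | None = None,
):
    """Goodness of fit vs the narrow-tuning grid as input tuning broadens.

    Returns a list of dict rows: width_2sigma_deg, mean_deviation,
    corr_coef, grid.  The reference is the base config's own (narrow)
    grid on the same seeds unless one is supplied.
    """
    if base is None:
        base = preset("fig2c", NetworkConfig(), weight=spec.lateral_weight)
    if reference_grid is None:
        reference_grid = _grid_for(base, spec)
    rows = []
    for width in spec.widths:
        cfg = NetworkConfig(
            bank=base.bank.with_width(width), ff_weight_r=base.ff_weight_r,
            ff_weight_i=base.ff_weight_i, lateral=base.lateral,
            rc_weight=base.rc_weight, depression=base.depression,
            relay=base.relay, inter=base.inter, cortical=base.cortical,
            adapt_all=base.adapt_all, input_refractory=base.input_refractory,
            dt=base.dt, strf_no=base.strf_no, unit=base.unit,
        )
        g = _grid_for(cfg, spec)
        dev, corr = goodness_of_fit(g, reference_grid)
        rows.append({"width_2sigma_deg": float(width), "mean_deviation": dev,
                     "corr_coef": corr, "grid": g})
    return rows


def run_multimasker(
    network: Network,
    target_az: float,
    masker_azs: list[float],
    spec: ExperimentSpec,
):
    """Discriminability with simultaneous maskers at several azimuths,
    alongside each single-masker baseline and the clean value.

    Each masker position gets independently seeded noise tokens, so
    simultaneous maskers are mutually independent (and, by default,
    refreshed per trial as in the grid simulations).
    """
    song1, song2, base_masker = make_stimuli(spec)
    tokens = {
        az: masker_tokens(base_masker, spec.n_trials,
                          child_int(spec.stim_seed, "mm", az),
                          spec.masker_gain, spec.masker_refresh)
        for az in masker_azs
    }

    def score(mask_positions, tag):
        sets = {}
        for sid, song in ((1, song1), (2, song2)):
            scenes = []
            for trial in range(spec.n_trials):
                sources = [SceneSource(song, target_az, "target")]
                for az in mask_positions:
                    sources.append(SceneSource(tokens[az][trial], az, "masker"))
                scenes.append(Scene(sources))
            cond_seed = child_int(spec.seed, "mm", tag, sid, target_az,
                                  *sorted(mask_positions))
            sets[sid], _ = network.run_trials(scenes, seed=cond_seed)
        return discriminability(sets[1], sets[2], tau=spec.tau,
                                seed=child_int(spec.seed, "mmdisc", tag))

    result = {
        "clean": score([], "clean"),
        "multi": score(list(masker_azs), "multi") if masker_azs else None,
        "single": {az: score([az], f"single{az}") for az in masker_azs},
    }
    if not masker_azs:
        result["multi"] = result["clean"]
    return result


# ---------------------------------------------------------------------------
# Coordinate-wise fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    config: NetworkConfig
    stage_objectives: dict
    trace: list          # (stage, parameter, value, objective) accepted steps
    mean_deviation: float
    corr_coef: float
    evaluations: int
    converged: bool = True


class _FrozenEvaluator:
    """Grid-cell simulator on frozen input spikes (deterministic objective).

    Input spikes depend only on the stimuli, azimuths, and STRF encoding
    -- none of the fitted parameters -- so they are generated once and
    every candidate config is integrated on identical inputs.
    """

    def __init__(self, template: NetworkConfig, spec: ExperimentSpec):
        self.spec = spec
        self.azimuths = tuple(float(a) for a in spec.azimuths)
        song1, song2, masker = make_stimuli(spec)
        tokens = masker_tokens(masker, spec.n_trials, spec.seed,
                               spec.masker_gain, spec.masker_refresh)
        net = build_network(template)
        self.inputs = {}
        for sid, song in ((1, song1), (2, song2)):
            for i, az_t in enumerate(self.azimuths):
                key = ("clean", sid, i)
                scenes = [Scene([SceneSource(song, az_t, "target")])] * spec.n_trials
                self.inputs[key] = net.input_spikes_for_scenes(
                    scenes, child_int(spec.seed, "fit", *key))
                for m, az_m in enumerate(self.azimuths):
                    key = ("masked", sid, i, m)
                    scenes = [
                        Scene([SceneSource(song, az_t, "target"),
                               SceneSource(tokens[trial], az_m, "masker")])
                        for trial in range(spec.n_trials)
                    ]
                    self.inputs[key] = net.input_spikes_for_scenes(
                        scenes, child_int(spec.seed, "fit", *key))
        self.evaluations = 0

    def cell(self, config: NetworkConfig, kind: str, i: int, m: int | None = None):
        """Discriminability of one grid cell under `config`."""
        net = Network(config)
        from .spikes import SpikeTrainSet

        sets = []
        for sid in (1, 2):
            key = (kind, sid, i) if m is None else (kind, sid, i, m)
            recs = net.run_from_input_spikes(self.inputs[key])
            sets.append(SpikeTrainSet([r.cortical_spikes for r in recs]))
        self.evaluations += 1
        return discriminability(
            sets[0], sets[1], tau=self.spec.tau,
            seed=child_int(self.spec.seed, "fitdisc", kind, i, -1 if m is None else m))

    def full_grid(self, config: NetworkConfig) -> DiscriminabilityGrid:
        """Final-report grid; not charged against the search budget."""
        count = self.evaluations
        n = len(self.azimuths)
        clean = np.array([self.cell(config, "clean", i) for i in range(n)])
        masked = np.array([[self.cell(config, "masked", i, m) for i in range(n)]
                           for m in range(n)])
        self.evaluations = count
        return DiscriminabilityGrid(clean, masked, self.azimuths)


def _line_search(values, objective, can_eval, refine: int = 4):
    """Deterministic coarse-to-fine 1-D minimization over `values`.

    `can_eval()` gates each objective call against the fitting budget.
    Returns (best_value, best_objective, history)."""
    history = []
    best_v, best_o = None, np.inf
    evaluated = []
    for v in values:
        if not can_eval():
            break
        o = objective(v)
        evaluated.append(v)
        history.append((v, o))
        if o < best_o:
            best_v, best_o = v, o
    if best_v is not None and refine and can_eval():
        vs = sorted(evaluated)
        idx = vs.index(best_v)
        lo = vs[max(idx - 1, 0)]
        hi = vs[min(idx + 1, len(vs) - 1)]
        for v in np.linspace(lo, hi, refine + 2)[1:-1]:
            if not can_eval():
                break
            o = objective(float(v))
            history.append((float(v), o))
            if o < best_o:
                best_v, best_o = float(v), o
    return best_v, best_o, history


def fit_to_grid(
    target: DiscriminabilityGrid,
    template: NetworkConfig,
    budget: int = 400,
    spec: ExperimentSpec | None = None,
) -> FitResult:
    """Staged coordinate-wise fit of a network config to a target grid.

    Stage 1 searches the cortical adaptation strength (0-0.2) to match the
    mean clean-row level; stage 2 searches each channel's feedforward
    weight to match its clean value; stage 3 searches each off-diagonal
    lateral weight to match its masked cell (the connection from the
    target channel onto the masker channel).  All stages integrate the
    network on frozen input spikes, so the objective is deterministic and
    non-increasing over accepted steps.
    """
    if budget < 20:
        raise ValueError("budget must be >= 20 evaluations")
    if spec is None:
        spec = ExperimentSpec()
    if tuple(spec.azimuths) != tuple(target.azimuths):
        spec = replace(spec, azimuths=tuple(target.azimuths))
    ev = _FrozenEvaluator(template, spec)
    n = len(spec.azimuths)
    cfg = NetworkConfig(
        bank=template.bank, ff_weight_r=template.ff_weight_r.copy(),
        ff_weight_i=template.ff_weight_i.copy(), lateral=template.lateral.copy(),
        rc_weight=template.rc_weight.copy(), depression=template.depression,
        relay=template.relay, inter=template.inter, cortical=template.cortical,
        adapt_all=template.adapt_all, input_refractory=template.input_refractory,
        dt=template.dt, strf_no=template.strf_no, unit=template.unit,
    )
    trace = []
    stage_objectives = {}
    exhausted = False
    can_eval = lambda: ev.evaluations < budget  # noqa: E731

    # -- stage 1: adaptation strength vs mean clean level ----------------
    clean_target_mean = float(np.mean(target.clean))

    def obj_adapt(a):
        trial = replace(cfg.cortical, adapt_strength=float(a))
        c2 = _with(cfg, cortical=trial)
        vals = [ev.cell(c2, "clean", i) for i in range(n)]
        return abs(float(np.mean(vals)) - clean_target_mean)

    cands = list(np.linspace(0.0, 0.2, 6))
    incumbent = float(cfg.cortical.adapt_strength)
    if incumbent not in cands:
        cands.append(incumbent)
    best_a, best_o, _ = _line_search(cands, obj_adapt, can_eval, refine=2)
    if best_a is not None:
        cfg = _with(cfg, cortical=replace(cfg.cortical, adapt_strength=float(best_a)))
        trace.append(("adaptation", "adapt_strength", float(best_a), best_o))
    stage_objectives["adaptation"] = best_o

    # -- stage 2: per-channel feedforward weight vs clean value ----------
    for i in range(n):
        if ev.evaluations >= budget:
            exhausted = True
            break
        t_val = float(target.clean[i])

        base_w = float(cfg.ff_weight_r[i])
        fi_ratio = float(cfg.ff_weight_i[i]) / base_w if base_w > 0 else 2.0

        def obj_ff(w, i=i, fi_ratio=fi_ratio):
            c2 = _with(cfg)
            c2.ff_weight_r[i] = float(w)
            c2.ff_weight_i[i] = fi_ratio * float(w)
            return abs(ev.cell(c2, "clean", i) - t_val)

        cands = sorted({round(base_w * f, 4) for f in (0.4, 0.7, 1.0, 1.3, 1.7)})
        w, o, _ = _line_search(cands, obj_ff, can_eval, refine=2)
        if w is not None:
            cfg.ff_weight_r[i] = w
            cfg.ff_weight_i[i] = fi_ratio * w
            trace.append(("feedforward", f"ff_weight[{i}]", w, o))
    stage_objectives["feedforward"] = (
        float(np.mean([abs(ev.cell(cfg, "clean", i) - target.clean[i])
                       for i in range(n)]))
        if ev.evaluations + n <= budget else None
    )

    # -- stage 3: lateral weights vs masked cells, per channel pair ------
    # The connection I_j -> R_k raises the (masker k, target j) cell and
    # lowers the reversed (masker j, target k) cell, so the two weights of
    # an unordered channel pair are fitted jointly against both cells.
    # Weight candidates form a geometric ladder: suppression saturates, so
    # coarse coverage up to strongly suppressing values beats resolution.
    ladder = [0.0, 2.0, 4.0, 8.0, 16.0, 32.0]
    for i in range(n):
        for m in range(i + 1, n):
            if ev.evaluations >= budget:
                exhausted = True
                break
            t_a = float(target.masked[m, i])  # raised by lateral[i, m]
            t_b = float(target.masked[i, m])  # raised by lateral[m, i]

            def pair_obj(c2, i=i, m=m):
                return (abs(ev.cell(c2, "masked", i, m) - t_a)
                        + abs(ev.cell(c2, "masked", m, i) - t_b))

            for j, k in ((i, m), (m, i)):

                def obj_lat(w, j=j, k=k):
                    c2 = _with(cfg)
                    c2.lateral[j, k] = float(w)
                    return pair_obj(c2)

                cands = list(ladder)
                incumbent = float(cfg.lateral[j, k])
                if incumbent not in cands:
                    cands.append(incumbent)
                w, o, _ = _line_search(cands, obj_lat, can_eval, refine=2)
                if w is not None:
                    cfg.lateral[j, k] = w
                    trace.append(("lateral", f"lateral[{j},{k}]", w, o))
        if exhausted:
            break

    if exhausted:
        warnings.warn("fit_to_grid: evaluation budget exhausted; "
                      "returning best configuration so far", RuntimeWarning)

    fitted_grid = ev.full_grid(cfg)
    mean_dev, corr = goodness_of_fit(fitted_grid, target)
    stage_objectives["final"] = mean_dev
    return FitResult(
        config=cfg, stage_objectives=stage_objectives, trace=trace,
        mean_deviation=mean_dev, corr_coef=corr,
        evaluations=ev.evaluations, converged=not exhausted,
    )


def _with(cfg: NetworkConfig, **over) -> NetworkConfig:
    kw = dict(
        bank=cfg.bank, ff_weight_r=cfg.ff_weight_r.copy(),
        ff_weight_i=cfg.ff_weight_i.copy(), lateral=cfg.lateral.copy(),
        rc_weight=cfg.rc_weight.copy(), depression=cfg.depression,
        relay=cfg.relay, inter=cfg.inter, cortical=cfg.cortical,
        adapt_all=cfg.adapt_all, input_refractory=cfg.input_refractory,
        dt=cfg.dt, strf_no=cfg.strf_no, unit=cfg.unit,
    )
    kw.update(over)
    return NetworkConfig(**kw)
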
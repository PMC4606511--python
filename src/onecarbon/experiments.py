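"""Virtual experiments: knockout/upregulation panels, input sweeps,
folate-deficiency sweeps with a Vmax-jitter envelope, and meal-driven
24-hour simulations.

All experiments compare perturbed steady states (or trajectories) against
the baseline steady state of the same parameter set.  The long-range
interaction toggle is available throughout; with ``lri=False`` the baseline
SAM is frozen into the three allosteric terms first (the clamp is a no-op
at the baseline itself).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import IDX, reaction_velocities
from .params import METHIONINE_CYCLE_VMAX_KEYS, ParameterSet
from .steady_state import FLUX_NAMES, SteadyStateReport, solve_steady_state
from .system import InputSchedule, simulate

__all__ = [
    "PerturbationSpec",
    "PerturbationResult",
    "MT_TARGETS",
    "run_perturbation",
    "knockout_panel",
    "methionine_sweep",
    "folate_sweep",
    "vmax_envelope",
    "meal_simulation",
]

#: Methyltransferases that can be perturbed.
MT_TARGETS = ("gnmt", "as3mt", "pemt", "gamt", "dnmt")

#: Concentrations (plus frac) tracked in perturbation reports.
TRACKED = ("sam", "m5", "gs", "frac")


@dataclass(frozen=True)
class PerturbationSpec:
    """One enzyme-level perturbation.

    ``multiplier`` scales the enzyme amount: 0 is a knockout, 20 is the
    DNMT upregulation experiment.  For GNMT the multiplier acts on the total
    protein (catalysis and folate binding together); for the other
    methyltransferases it scales the cell-effective Vmax.
    """

    target: str
    multiplier: float
    lri: bool = True

    def __post_init__(self) -> None:
        if self.target not in MT_TARGETS:
            raise ValueError(
                f"unknown perturbation target {self.target!r}; "
                f"choose from {MT_TARGETS}"
            )
        if self.multiplier < 0:
            raise ValueError("multiplier must be >= 0")

    def apply(self, p: ParameterSet) -> ParameterSet:
        if self.target == "gnmt":
            return p.with_updates({"gnmt.total": p["gnmt.total"] * self.multiplier})
        key = f"{self.target}.vmax_cell"
        return p.with_updates({key: p[key] * self.multiplier})


@dataclass
class PerturbationResult:
    spec: PerturbationSpec
    baseline: SteadyStateReport
    perturbed: SteadyStateReport
    pct_flux: dict[str, float]
    pct_tracked: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"quantity": k, "kind": "flux", "pct_change": v}
            for k, v in self.pct_flux.items()
        ] + [
            {"quantity": k, "kind": "tracked", "pct_change": v}
            for k, v in self.pct_tracked.items()
        ]
        df = pd.DataFrame(rows)
        df.insert(0, "target", self.spec.target)
        df.insert(1, "multiplier", self.spec.multiplier)
        df.insert(2, "lri", self.spec.lri)
        return df


def _pct(new: float, old: float) -> float:
    if old == 0.0:
        return 0.0 if new == 0.0 else float("inf") * np.sign(new)
    return 100.0 * (new - old) / old


def run_perturbation(
    spec: PerturbationSpec,
    p: ParameterSet,
    baseline: SteadyStateReport | None = None,
) -> PerturbationResult:
    """Steady-state response to one enzyme perturbation.

    The baseline is the unperturbed steady state with the long-range
    interactions on; it is also the clamp point when ``spec.lri`` is False
    (at which the clamp changes nothing, so the baseline is shared by both
    toggles).
    """
    if baseline is None:
        baseline = solve_steady_state(p, lri=True)
    sam_frozen = baseline.concentration("sam")
    p_pert = spec.apply(p)
    perturbed = solve_steady_state(
        p_pert,
        lri=spec.lri,
        init=baseline.state,
        sam_frozen=None if spec.lri else sam_frozen,
    )
    pct_flux = {
        k: _pct(perturbed.fluxes[k], baseline.fluxes[k]) for k in FLUX_NAMES
    }
    pct_tracked = {
        "sam": _pct(perturbed.concentration("sam"), baseline.concentration("sam")),
        "m5": _pct(perturbed.concentration("m5"), baseline.concentration("m5")),
        "gs": _pct(perturbed.concentration("gs"), baseline.concentration("gs")),
        "frac": _pct(perturbed.frac, baseline.frac),
    }
    return PerturbationResult(spec, baseline, perturbed, pct_flux, pct_tracked)


def knockout_panel(
    p: ParameterSet,
    lri: bool = True,
    specs: tuple[tuple[str, float], ...] = (
        ("pemt", 0.0), ("gamt", 0.0), ("gnmt", 0.0), ("dnmt", 20.0)
    ),
) -> pd.DataFrame:
    """The knockout/upregulation panel: PEMT, GAMT and GNMT knockouts plus
    20-fold DNMT upregulation, as percentage changes from baseline."""
    baseline = solve_steady_state(p, lri=True)
    frames = []
    for target, mult in specs:
        res = run_perturbation(PerturbationSpec(target, mult, lri), p, baseline)
        frames.append(res.to_frame())
    return pd.concat(frames, ignore_index=True)


def methionine_sweep(
    inputs: np.ndarray, p: ParameterSet, lri: bool = True
) -> pd.DataFrame:
    """Steady-state SAM (and fluxes) as a function of methionine input."""
    inputs = np.asarray(inputs, dtype=float)
    sam_frozen = None
    if not lri:
        sam_frozen = solve_steady_state(p, lri=True).concentration("sam")
    rows = []
    warm = None
    for rate in inputs:
        p_i = p.with_updates({"input.methionine": rate})
        try:
            rep = solve_steady_state(p_i, lri=lri, init=warm, sam_frozen=sam_frozen)
        except ArithmeticError as err:  # pragma: no cover - extreme inputs
            import warnings

            warnings.warn(f"no steady state at input {rate}: {err}")
            continue
        warm = rep.state
        rows.append(
            {
                "methionine_input": rate,
                "lri": lri,
                "sam": rep.concentration("sam"),
                "m5": rep.concentration("m5"),
                "cycle_flux": rep.cycle_flux,
                "total_methylation": rep.total_methylation,
                "frac": rep.frac,
                "cbs": rep.fluxes["cbs"],
            }
        )
    return pd.DataFrame(rows)


def folate_sweep(
    folate_totals: np.ndarray, p: ParameterSet, lri: bool = True
) -> pd.DataFrame:
    """Steady-state SAM and total methylation flux versus total folate."""
    folate_totals = np.asarray(folate_totals, dtype=float)
    sam_frozen = None
    if not lri:
        sam_frozen = solve_steady_state(p, lri=True).concentration("sam")
    rows = []
    warm = None
    for tot in folate_totals:
        p_i = p.with_updates({"folate.total": tot})
        try:
            rep = solve_steady_state(p_i, lri=lri, init=warm, sam_frozen=sam_frozen)
        except (ArithmeticError, ValueError) as err:  # pragma: no cover
            import warnings

            warnings.warn(f"no steady state at folate total {tot}: {err}")
            continue
        warm = None  # totals change; re-projected fresh start is as fast
        rows.append(
            {
                "folate_total": tot,
                "lri": lri,
                "sam": rep.concentration("sam"),
                "m5": rep.concentration("m5"),
                "total_methylation": rep.total_methylation,
                "frac": rep.frac,
            }
        )
    return pd.DataFrame(rows)


def vmax_envelope(
    folate_totals: np.ndarray,
    p: ParameterSet,
    lri: bool = True,
    n_reps: int = 10,
    jitter: float = 0.1,
    seed: int = 0,
) -> dict:
    """Sensitivity envelope of the folate sweep under Vmax jitter.

    Each replicate multiplies the 11 methionine-cycle Vmax values by
    independent draws from [1 - jitter, 1 + jitter] (one RNG stream; the
    replicate index is the draw order) and recomputes the folate sweep.  The
    envelope is the pointwise min/max over replicates.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not 0.0 <= jitter < 1.0:
        raise ValueError("jitter must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    base = folate_sweep(folate_totals, p, lri=lri)
    curves_sam, curves_tm = [], []
    for _ in range(n_reps):
        mults = rng.uniform(1.0 - jitter, 1.0 + jitter, size=len(METHIONINE_CYCLE_VMAX_KEYS))
        p_j = p.with_updates(
            {k: p[k] * m for k, m in zip(METHIONINE_CYCLE_VMAX_KEYS, mults)}
        )
        df = folate_sweep(folate_totals, p_j, lri=lri)
        curves_sam.append(df["sam"].to_numpy())
        curves_tm.append(df["total_methylation"].to_numpy())
    sam = np.vstack(curves_sam)
    tm = np.vstack(curves_tm)
    return {
        "folate_total": base["folate_total"].to_numpy(),
        "lri": lri,
        "seed": seed,
        "jitter": jitter,
        "n_reps": n_reps,
        "base_sam": base["sam"].to_numpy(),
        "base_total_methylation": base["total_methylation"].to_numpy(),
        "sam_min": sam.min(axis=0),
        "sam_max": sam.max(axis=0),
        "total_methylation_min": tm.min(axis=0),
        "total_methylation_max": tm.max(axis=0),
    }


def meal_simulation(
    schedule: InputSchedule,
    days: int,
    p: ParameterSet,
    lri: bool = True,
    dt: float = 0.1,
) -> pd.DataFrame:
    """Trajectories of states and fluxes under a daily meal schedule.

    Starts from the constant-input baseline steady state, integrates
    ``days`` 24-hour cycles and discards the first day as a transient.
    Returns a tidy frame with time (hours), the 13 states, every net flux
    and the transsulfuration fraction.
    """
    if days < 2:
        raise ValueError("days must be >= 2 (the first day is discarded)")
    baseline = solve_steady_state(p, lri=True)
    sam_frozen = None if lri else baseline.concentration("sam")
    t_eval = np.arange(0.0, days * 24.0 + dt / 2, dt)
    t, y = simulate(
        p, (0.0, days * 24.0), baseline.state, schedule,
        lri=lri, sam_frozen=sam_frozen, t_eval=t_eval,
    )
    keep = t >= 24.0
    t, y = t[keep], y[:, keep]
    from .kinetics import STATE_NAMES
    from .system import methionine_input

    rows = {"t": t}
    for name in STATE_NAMES:
        rows[name] = y[IDX[name]]
    flux_arr = {k: np.empty(t.size) for k in FLUX_NAMES}
    frac = np.empty(t.size)
    for j in range(t.size):
        v = reaction_velocities(y[:, j], p, lri=lri, sam_frozen=sam_frozen)
        for k in FLUX_NAMES:
            flux_arr[k][j] = v[k]
        frac[j] = v["cbs"] / v["sahh"] if v["sahh"] != 0 else np.nan
    rows.update(flux_arr)
    rows["frac"] = frac
    rows["methionine_input"] = [methionine_input(tt, schedule) for tt in t]
    return pd.DataFrame(rows)


def relative_amplitude(series: np.ndarray) -> float:
    """Peak-to-trough amplitude relative to the mean; the flux-variability
    measure used for the meal experiment."""
    s = np.asarray(series, dtype=float)
    m = s.mean()
    if m == 0:
        return 0.0
    return float((s.max() - s.min()) / m)
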
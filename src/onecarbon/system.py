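"""Assembly of the full 13-variable mass-balance ODE system.

Each state component changes at the rate (sum of inflowing reaction
velocities) minus (sum of outflowing velocities).  The SAM equation is
exactly  V_MATI + V_MATIII - V_GNMT - V_AS3MT - V_PEMT - V_GAMT - V_DNMT.

Two quantities are conserved exactly by construction along any trajectory:
the total GNMT protein (free + singly + doubly bound) and the total folate
pool (free folates + one 5mTHF per singly bound + two per doubly bound
GNMT).

The long-range-interaction (lri) toggle: with ``lri=False`` the three
allosteric terms through which SAM acts at distant points of the network
(activation of CBS, inhibition of BHMT, inhibition of MTHFR) read the
baseline steady-state SAM instead of the current SAM, while every
mass-balance flux stays dynamic.  Freeze the baseline with
:func:`freeze_baseline` before using ``lri=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import kinetics
from .kinetics import IDX, STATE_NAMES, reaction_velocities
from .params import ParameterSet

__all__ = [
    "STATE_NAMES",
    "IDX",
    "InputSchedule",
    "methionine_input",
    "assemble_rhs",
    "freeze_baseline",
    "simulate",
    "folate_pool",
    "gnmt_pool",
]


@dataclass(frozen=True)
class InputSchedule:
    """Methionine input forcing (uM/hr).

    ``constant`` mode returns ``rate`` at all times.  ``meal`` mode is a
    24-hour-cyclic piecewise-constant profile: a fasting baseline rate, a
    raised rate for ``window`` hours after breakfast and lunch, and a higher
    rate for ``window`` hours after dinner.  Meal clock times are
    configurable; the defaults are breakfast 07:00, lunch 12:00, dinner
    18:00.
    """

    mode: str = "constant"
    rate: float = 50.0
    fasting_rate: float = 100.0 / 3.0
    meal_rate: float = 200.0 / 3.0
    dinner_rate: float = 100.0
    breakfast: float = 7.0
    lunch: float = 12.0
    dinner: float = 18.0
    window: float = 3.0

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "meal"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        for name in ("rate", "fasting_rate", "meal_rate", "dinner_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def segments(self) -> list[tuple[float, float, float]]:
        """(start hr, end hr, rate) covering one 24 h cycle without overlap."""
        if self.mode == "constant":
            return [(0.0, 24.0, self.rate)]
        b, l, d, w = self.breakfast, self.lunch, self.dinner, self.window
        return [
            (0.0, b, self.fasting_rate),
            (b, b + w, self.meal_rate),
            (b + w, l, self.fasting_rate),
            (l, l + w, self.meal_rate),
            (l + w, d, self.fasting_rate),
            (d, d + w, self.dinner_rate),
            (d + w, 24.0, self.fasting_rate),
        ]

    def breakpoints(self) -> np.ndarray:
        return np.unique([t for seg in self.segments() for t in seg[:2]])


def methionine_input(t: float, schedule: InputSchedule) -> float:
    """Methionine input rate (uM/hr) at time ``t`` (hours)."""
    if t < 0:
        raise ValueError("time must be >= 0")
    if schedule.mode == "constant":
        return schedule.rate
    tau = t % 24.0
    for start, end, rate in schedule.segments():
        if start <= tau < end:
            return rate
    return schedule.fasting_rate  # tau == 24.0 edge


def folate_pool(state: np.ndarray) -> float:
    """Total folate accounted by a state: free folates plus GNMT-bound
    5mTHF (one per singly, two per doubly bound enzyme)."""
    y = np.asarray(state, dtype=float)
    free = y[IDX["thf"]] + y[IDX["ch2"]] + y[IDX["ch"]] + y[IDX["f10"]] \
        + y[IDX["dhf"]] + y[IDX["m5"]]
    return free + y[IDX["gs"]] + 2.0 * y[IDX["gd"]]


def gnmt_pool(state: np.ndarray) -> float:
    y = np.asarray(state, dtype=float)
    return y[IDX["g"]] + y[IDX["gs"]] + y[IDX["gd"]]


def assemble_rhs(
    state: np.ndarray,
    t: float,
    p: ParameterSet,
    schedule: InputSchedule | None = None,
    lri: bool = True,
    sam_frozen: float | None = None,
) -> np.ndarray:
    """Time derivatives (uM/hr) of the 13 state variables."""
    y = np.asarray(state, dtype=float)
    if y.shape != (len(STATE_NAMES),):
        raise ValueError(f"state must have {len(STATE_NAMES)} components")
    if not np.all(np.isfinite(y)):
        bad = STATE_NAMES[int(np.argmax(~np.isfinite(y)))]
        raise ArithmeticError(f"non-finite state component: {bad}")
    if np.any(y < -1e-6):
        bad = STATE_NAMES[int(np.argmin(y))]
        raise ArithmeticError(f"negative state component: {bad} = {y.min():.3e}")
    if schedule is None:
        schedule = InputSchedule(mode="constant", rate=p["input.methionine"])

    v = reaction_velocities(y, p, lri=lri, sam_frozen=sam_frozen)
    metin = methionine_input(t, schedule)

    k1, k2 = p["binding.k1"], p["binding.k2"]
    k3, k4 = p["binding.k3"], p["binding.k4"]
    m5 = max(y[IDX["m5"]], 0.0)
    g, gs, gd = (max(y[IDX[k]], 0.0) for k in ("g", "gs", "gd"))
    bind1 = k1 * m5 * g - k2 * gs  # net first-site binding flux
    bind2 = k3 * gs * m5 - k4 * gd  # net second-site binding flux

    mt_total = v["gnmt"] + v["as3mt"] + v["pemt"] + v["gamt"] + v["dnmt"]

    dy = np.empty_like(y)
    dy[IDX["met"]] = metin + v["bhmt"] + v["ms"] - v["mati"] - v["matiii"]
    dy[IDX["sam"]] = v["mati"] + v["matiii"] - mt_total
    dy[IDX["sah"]] = mt_total - v["sahh"]
    dy[IDX["hcy"]] = v["sahh"] - v["cbs"] - v["bhmt"] - v["ms"]
    dy[IDX["thf"]] = (
        v["ms"] + v["ftd"] + v["pgt"] + v["aicart"] + v["dhfr"]
        - v["shmt"] - v["ne"] - v["fts"]
    )
    dy[IDX["ch2"]] = v["shmt"] + v["ne"] - v["mthfr"] - v["ts"] - v["mtd"]
    dy[IDX["ch"]] = v["mtd"] - v["mtch"]
    dy[IDX["f10"]] = v["mtch"] + v["fts"] - v["ftd"] - v["pgt"] - v["aicart"]
    dy[IDX["dhf"]] = v["ts"] - v["dhfr"]
    dy[IDX["m5"]] = v["mthfr"] - v["ms"] - bind1 - bind2
    dy[IDX["g"]] = -bind1
    dy[IDX["gs"]] = bind1 - bind2
    dy[IDX["gd"]] = bind2
    return dy


def freeze_baseline(p: ParameterSet) -> float:
    """Baseline steady-state SAM (uM) for clamping the long-range terms.

    Solves the default-input steady state with the long-range interactions
    on and returns its SAM; idempotent for a given parameter set.
    """
    from .steady_state import solve_steady_state  # local: avoid import cycle

    report = solve_steady_state(p, lri=True)
    return float(report.state[IDX["sam"]])


def simulate(
    p: ParameterSet,
    t_span: tuple[float, float],
    init: np.ndarray,
    schedule: InputSchedule | None = None,
    lri: bool = True,
    sam_frozen: float | None = None,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
):
    """Integrate the system over ``t_span`` hours with a stiff solver.

    Piecewise-constant input is handled by integrating segment by segment
    across the schedule's breakpoints, so the solver never steps over a
    discontinuity.  Returns ``(t, y)`` with ``y`` of shape (13, len(t)).
    """
    if schedule is None:
        schedule = InputSchedule(mode="constant", rate=p["input.methionine"])

    def rhs(t, y):
        return assemble_rhs(y, t, p, schedule, lri=lri, sam_frozen=sam_frozen)

    t0, t1 = t_span
    if schedule.mode == "constant":
        edges = np.array([t0, t1])
    else:
        cyc = schedule.breakpoints()
        day0 = np.floor(t0 / 24.0)
        days = np.arange(day0, np.ceil(t1 / 24.0) + 1)
        edges = np.unique(np.concatenate([[t0, t1], (days[:, None] * 24.0 + cyc).ravel()]))
        edges = edges[(edges >= t0) & (edges <= t1)]

    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    y0 = np.asarray(init, dtype=float)
    for a, b in zip(edges[:-1], edges[1:]):
        if b <= a:
            continue
        dense = t_eval is not None
        sol = solve_ivp(
            rhs, (a, b), y0, method="LSODA", rtol=rtol, atol=atol, dense_output=dense
        )
        if not sol.success:
            raise ArithmeticError(f"integration failed on [{a}, {b}]: {sol.message}")
        y0 = sol.y[:, -1]
        if dense:
            pts = t_eval[(t_eval >= a) & (t_eval < b)]
            if pts.size:
                ts.append(pts)
                ys.append(sol.sol(pts))
        else:
            ts.append(sol.t)
            ys.append(sol.y)
    if t_eval is not None and t_eval.size and t_eval[-1] == edges[-1]:
        ts.append(np.array([edges[-1]]))
        ys.append(y0[:, None])
    t = np.concatenate(ts) if ts else np.array([t1])
    y = np.concatenate(ys, axis=1) if ys else y0[:, None]
    return t, y
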
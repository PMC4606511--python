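"""Rate laws for every reaction in the network.

Two layers live here:

* the five methyltransferase rate laws in their in-vitro form
  (:func:`v_gnmt` ... :func:`v_dnmt`), parameterized by the measured Km/Ki
  and the in-vitro Vmax — used for analysis of functional shape;
* :func:`reaction_velocities`, which evaluates the full cellular model (all
  22 reactions) at a 13-component state vector, using the co-substrate-folded
  ``*.vmax_cell`` / anchored Vmax values.

All concentrations are uM and all velocities uM/hr.  Concentrations below
1e-12 uM are treated as exactly zero to avoid sign flips from round-off.
"""

from __future__ import annotations

import numpy as np

from .params import (
    ParameterSet,
    REFERENCE_CONCENTRATIONS,
    reference_binding_occupancy,
)

__all__ = [
    "STATE_NAMES",
    "IDX",
    "reference_state",
    "v_gnmt",
    "v_as3mt",
    "v_pemt",
    "v_gamt",
    "v_dnmt",
    "reaction_velocities",
    "regulated_velocities",
    "supplementary_velocities",
]

#: Order of the 13 state variables (concentrations, uM).
STATE_NAMES = (
    "met",  # methionine
    "sam",  # S-adenosylmethionine
    "sah",  # S-adenosylhomocysteine
    "hcy",  # homocysteine
    "thf",  # tetrahydrofolate
    "ch2",  # 5,10-methylene-THF
    "ch",  # 5,10-methenyl-THF
    "f10",  # 10-formyl-THF
    "dhf",  # dihydrofolate
    "m5",  # free 5-methyl-THF
    "g",  # free GNMT
    "gs",  # 5mTHF-GNMT (singly bound)
    "gd",  # 5mTHF-GNMT-5mTHF (doubly bound)
)

IDX = {name: i for i, name in enumerate(STATE_NAMES)}

_ZERO_GUARD = 1e-12


def reference_state(p: ParameterSet) -> np.ndarray:
    """The reference operating point as a 13-vector.

    DHF closes the folate balance: free folates + singly bound + twice the
    doubly bound 5mTHF sum to the total folate pool.
    """
    c = REFERENCE_CONCENTRATIONS
    g, gs, gd = reference_binding_occupancy(p)
    dhf = p["folate.total"] - (
        c["thf"] + c["ch2"] + c["ch"] + c["f10"] + c["m5"] + gs + 2.0 * gd
    )
    if dhf <= 0:
        raise ValueError(
            "reference folate pools exceed folate.total; cannot close DHF balance"
        )
    return np.array(
        [
            c["met"], c["sam"], c["sah"], c["hcy"],
            c["thf"], c["ch2"], c["ch"], c["f10"], dhf, c["m5"],
            g, gs, gd,
        ]
    )


# --------------------------------------------------------------------------
# In-vitro methyltransferase rate laws
# --------------------------------------------------------------------------
def _check_nonneg(**concs: float) -> None:
    for name, v in concs.items():
        if v < 0:
            raise ValueError(f"negative concentration for {name}: {v}")


def v_gnmt(sam: float, sah: float, gnmt_free: float, gnmt_single: float,
           p: ParameterSet) -> float:
    """GNMT velocity (uM/hr): cooperative in SAM (Hill n), competitive SAH
    inhibition, catalysis carried by free plus half-active singly bound
    enzyme."""
    _check_nonneg(sam=sam, sah=sah, gnmt_free=gnmt_free, gnmt_single=gnmt_single)
    vmax_eff = p["gnmt.vmax"] * (
        p["activity.w_free"] * gnmt_free + p["activity.w_single"] * gnmt_single
    )
    n = p["gnmt.hill"]
    kapp = p["gnmt.km_sam"] * (1.0 + sah / p["gnmt.ki_sah"])
    return vmax_eff * sam**n / (kapp**n + sam**n)


def v_as3mt(sam: float, sah: float, p: ParameterSet) -> float:
    """AS3MT velocity (uM/hr): Michaelis-Menten in SAM with competitive SAH
    inhibition (first arsenic methylation step)."""
    _check_nonneg(sam=sam, sah=sah)
    kapp = p["as3mt.km_sam"] * (1.0 + sah / p["as3mt.ki_sah"])
    return p["as3mt.vmax"] * sam / (kapp + sam)


def v_pemt(sam: float, sah: float, p: ParameterSet) -> float:
    """PEMT velocity (uM/hr): Michaelis-Menten in SAM, noncompetitive SAH
    inhibition."""
    _check_nonneg(sam=sam, sah=sah)
    return (
        p["pemt.vmax"] * sam
        / ((p["pemt.km_sam"] + sam) * (1.0 + sah / p["pemt.ki_sah"]))
    )


def v_gamt(sam: float, sah: float, p: ParameterSet) -> float:
    """GAMT velocity (uM/hr): Michaelis-Menten in SAM, competitive SAH
    inhibition."""
    _check_nonneg(sam=sam, sah=sah)
    kapp = p["gamt.km_sam"] * (1.0 + sah / p["gamt.ki_sah"])
    return p["gamt.vmax"] * sam / (kapp + sam)


def v_dnmt(sam: float, sah: float, p: ParameterSet) -> float:
    """DNMT velocity (uM/hr): Michaelis-Menten in SAM, competitive SAH
    inhibition.  Km << typical SAM, so the velocity is nearly flat in SAM."""
    _check_nonneg(sam=sam, sah=sah)
    kapp = p["dnmt.km_sam"] * (1.0 + sah / p["dnmt.ki_sah"])
    return p["dnmt.vmax"] * sam / (kapp + sam)


# --------------------------------------------------------------------------
# Full cellular model
# --------------------------------------------------------------------------
def _mm(s: float, km: float) -> float:
    return s / (km + s)


def reaction_velocities(
    state: np.ndarray,
    p: ParameterSet,
    lri: bool = True,
    sam_frozen: float | None = None,
) -> dict[str, float]:
    """Evaluate every reaction velocity of the cellular model at ``state``.

    Parameters
    ----------
    state:
        13-vector in :data:`STATE_NAMES` order (uM).
    lri:
        Long-range-interaction toggle.  With ``lri=False`` the three
        allosteric terms through which SAM acts at a distance (CBS
        activation, BHMT inhibition, MTHFR inhibition) read ``sam_frozen``
        instead of the current SAM; everything else stays dynamic.
    sam_frozen:
        Baseline steady-state SAM (uM); required when ``lri=False``.

    Returns
    -------
    dict mapping reaction name to net velocity (uM/hr); reversible reactions
    additionally report their gross legs under ``<name>_f`` / ``<name>_r``.
    """
    y = np.asarray(state, dtype=float)
    y = np.where(y < _ZERO_GUARD, 0.0, y)
    met, sam, sah, hcy, thf, ch2, ch, f10, dhf, m5, g, gs, gd = y

    if lri:
        sam_reg = sam
    else:
        if sam_frozen is None:
            raise RuntimeError(
                "long-range interactions are off but no baseline SAM has been "
                "frozen; compute the baseline steady state first"
            )
        sam_reg = sam_frozen

    v: dict[str, float] = {}

    # methionine activation
    v["mati"] = (
        p["mati.vmax"] * _mm(met, p["mati.km_met"])
        * (p["mati.inhib_base"] + p["mati.inhib_amp"] * np.exp(-p["mati.inhib_rate"] * sam))
    )
    act = sam / (sam + p["matiii.act_ks"])
    km1 = p["matiii.km1_base"] / (1.0 + p["matiii.act_amp"] * act * act)
    v["matiii"] = p["matiii.vmax"] / (
        1.0 + km1 * p["matiii.km2"] / (met * met + met * p["matiii.km2"])
        if met > 0 else np.inf
    )

    # the five methyltransferases (cell-effective Vmax)
    active_gnmt = (
        p["activity.w_free"] * g
        + p["activity.w_single"] * gs
        + p["activity.w_double"] * gd
    )
    n = p["gnmt.hill"]
    kapp = p["gnmt.km_sam_cell"] * (1.0 + sah / p["gnmt.ki_sah"])
    v["gnmt"] = p["gnmt.vmax_cell"] * active_gnmt * sam**n / (kapp**n + sam**n)
    v["as3mt"] = (
        p["as3mt.vmax_cell"] * sam
        / (p["as3mt.km_sam"] * (1.0 + sah / p["as3mt.ki_sah"]) + sam)
    )
    v["pemt"] = (
        p["pemt.vmax_cell"] * sam
        / ((p["pemt.km_sam"] + sam) * (1.0 + sah / p["pemt.ki_sah"]))
    )
    v["gamt"] = (
        p["gamt.vmax_cell"] * sam
        / (p["gamt.km_sam"] * (1.0 + sah / p["gamt.ki_sah"]) + sam)
    )
    v["dnmt"] = (
        p["dnmt.vmax_cell"] * sam
        / (p["dnmt.km_sam"] * (1.0 + sah / p["dnmt.ki_sah"]) + sam)
    )

    # SAH <-> Hcy (net reversible)
    v["sahh_f"] = p["sahh.vmax_f"] * _mm(sah, p["sahh.km_sah"])
    v["sahh_r"] = p["sahh.vmax_r"] * _mm(hcy, p["sahh.km_hcy"])
    v["sahh"] = v["sahh_f"] - v["sahh_r"]

    # homocysteine disposal / remethylation; CBS and BHMT carry the
    # long-range SAM terms
    ka = p["cbs.ka_sam"]
    hc = p["cbs.hill"]
    v["cbs"] = (
        p["cbs.vmax"] * _mm(hcy, p["cbs.km_hcy"])
        * sam_reg**hc / (ka**hc + sam_reg**hc)
    )
    kb = p["bhmt.ki_sam"]
    hb = p["bhmt.hill"]
    v["bhmt"] = (
        p["bhmt.vmax"] * _mm(hcy, p["bhmt.km_hcy"])
        * kb**hb / (kb**hb + sam_reg**hb)
    )
    v["ms"] = p["ms.vmax"] * _mm(m5, p["ms.km_5mthf"]) * _mm(hcy, p["ms.km_hcy"])

    # folate cycle; MTHFR carries the long-range SAM inhibition
    km_i = p["mthfr.ki_sam"]
    hm = p["mthfr.hill"]
    v["mthfr"] = (
        p["mthfr.vmax"] * _mm(ch2, p["mthfr.km_ch2"])
        * km_i**hm / (km_i**hm + sam_reg**hm)
    )
    v["shmt_f"] = p["shmt.vmax_f"] * _mm(thf, p["shmt.km_thf"])
    v["shmt_r"] = p["shmt.vmax_r"] * _mm(ch2, p["shmt.km_ch2"])
    v["shmt"] = v["shmt_f"] - v["shmt_r"]
    v["ne_f"] = p["ne.k_f"] * thf
    v["ne_r"] = p["ne.k_r"] * ch2
    v["ne"] = v["ne_f"] - v["ne_r"]
    v["mtd_f"] = p["mtd.vmax_f"] * _mm(ch2, p["mtd.km_ch2"])
    v["mtd_r"] = p["mtd.vmax_r"] * _mm(ch, p["mtd.km_ch"])
    v["mtd"] = v["mtd_f"] - v["mtd_r"]
    v["mtch_f"] = p["mtch.vmax_f"] * _mm(ch, p["mtch.km_ch"])
    v["mtch_r"] = p["mtch.vmax_r"] * _mm(f10, p["mtch.km_f10"])
    v["mtch"] = v["mtch_f"] - v["mtch_r"]
    v["fts"] = p["fts.vmax"] * _mm(thf, p["fts.km_thf"])
    v["ftd"] = p["ftd.vmax"] * _mm(f10, p["ftd.km_f10"])
    v["pgt"] = p["pgt.vmax"] * _mm(f10, p["pgt.km_f10"])
    v["aicart"] = p["aicart.vmax"] * _mm(f10, p["aicart.km_f10"])
    v["ts"] = p["ts.vmax"] * _mm(ch2, p["ts.km_ch2"])
    v["dhfr"] = p["dhfr.vmax"] * _mm(dhf, p["dhfr.km_dhf"])

    return v


def regulated_velocities(
    state: np.ndarray,
    p: ParameterSet,
    lri: bool = True,
    sam_frozen: float | None = None,
) -> dict[str, float]:
    """Velocities of the three enzymes under long-range SAM control
    (CBS, BHMT, MTHFR)."""
    v = reaction_velocities(state, p, lri=lri, sam_frozen=sam_frozen)
    return {k: v[k] for k in ("cbs", "bhmt", "mthfr")}


def supplementary_velocities(state: np.ndarray, p: ParameterSet) -> dict[str, float]:
    """Velocities of the non-methyltransferase reactions (net values)."""
    v = reaction_velocities(state, p)
    keys = (
        "mati", "matiii", "sahh", "ms", "bhmt", "cbs", "mthfr", "shmt", "ts",
        "dhfr", "mtd", "mtch", "fts", "ftd", "pgt", "aicart", "ne",
    )
    return {k: v[k] for k in keys}
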
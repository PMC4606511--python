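"""In-silico knockouts and upregulation, with and without the long-range
interactions.

Knocks out PEMT, GAMT or GNMT, or upregulates DNMT 20-fold, and prints the
percentage change of each methyltransferase flux and of SAM, free 5mTHF,
singly bound GNMT and the transsulfuration fraction.  With the long-range
interactions on, GNMT absorbs most of the change (the salvage pathway) and
the other fluxes move modestly; with them off, SAM swings far more while
the folate side does not move at all.
"""

from onecarbon import default_parameters, knockout_panel

p = default_parameters()
for lri in (True, False):
    print(f"\nlong-range interactions {'ON' if lri else 'OFF'}")
    df = knockout_panel(p, lri=lri)
    keep = df["quantity"].isin(
        ["gnmt", "pemt", "gamt", "dnmt", "as3mt", "sam", "m5", "gs", "frac"]
    )
    piv = df[keep].pivot_table(
        index=["target", "multiplier"], columns="quantity", values="pct_change"
    )[["gnmt", "pemt", "gamt", "dnmt", "as3mt", "sam", "m5", "gs", "frac"]]
    print(piv.round(1).to_string())
print(
    "\n-> e.g. PEMT knockout: SAM up ~24 %, 5mTHF down ~16 %, GNMT flux up a"
    "\n   lot while GAMT rises only ~18 %; without the interactions every"
    "\n   change is larger (GNMT knockout: GAMT +122 % vs +54 %)."
)
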
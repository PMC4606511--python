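config_version: 1
activity.w_double: 0.0  # [-] relative activity of doubly bound GNMT
activity.w_free: 1.0  # [-] relative activity of free GNMT
activity.w_single: 0.5  # [-] relative activity of singly bound GNMT
aicart.km_f10: 6.0  # [uM] AICART Km for 10f-THF
aicart.vmax: 3.7222222222222228  # [uM/hr] AICART Vmax (AICAR folded in)
as3mt.ki_sah: 10.0  # [uM] AS3MT competitive Ki for SAH
as3mt.km_sam: 50.0  # [uM] AS3MT Km for SAM
as3mt.vmax: 5.0  # [uM/hr] AS3MT Vmax (first arsenic methylation)
as3mt.vmax_cell: 4.98863579474343  # [uM/hr] AS3MT Vmax with arsenic/GSH folded in
bhmt.hill: 3.0  # [-] BHMT Hill coefficient for SAM inhibition
bhmt.ki_sam: 60.0  # [uM] BHMT allosteric inhibition constant for SAM
bhmt.km_hcy: 12.0  # [uM] BHMT Km for Hcy
bhmt.vmax: 177.87852958024328  # [uM/hr] BHMT Vmax (betaine folded in)
binding.k1: 50.0  # [1/(uM*hr)] association, 5mTHF + GNMT -> 5mTHF-GNMT
binding.k2: 1.0  # [1/hr] dissociation, 5mTHF-GNMT -> 5mTHF + GNMT
binding.k3: 1.0  # [1/(uM*hr)] association, 5mTHF-GNMT + 5mTHF -> doubly bound
binding.k4: 1.6  # [1/hr] dissociation of the doubly bound complex
cbs.hill: 3.0  # [-] CBS Hill coefficient for SAM activation
cbs.ka_sam: 15.0  # [uM] CBS allosteric activation constant for SAM
cbs.km_hcy: 1000.0  # [uM] CBS Km for Hcy
cbs.vmax: 27486.447766777972  # [uM/hr] CBS Vmax (serine folded in)
dhfr.km_dhf: 0.5  # [uM] DHFR Km for DHF
dhfr.vmax: 12.97959755222031  # [uM/hr] DHFR Vmax (NADPH folded in)
dnmt.ki_sah: 1.4  # [uM] DNMT competitive Ki for SAH
dnmt.km_sam: 1.4  # [uM] DNMT Km for SAM
dnmt.vmax: 12.5  # [uM/hr] DNMT Vmax
dnmt.vmax_cell: 2.5024196912807675  # [uM/hr] DNMT Vmax with DNA substrate folded in
folate.total: 20.0  # [uM] total liver folate pool (free + GNMT-bound 5mTHF)
ftd.km_f10: 20.0  # [uM] FTD Km for 10f-THF
ftd.vmax: 59.38271604938272  # [uM/hr] FTD Vmax
fts.km_thf: 3.0  # [uM] FTS Km for THF
fts.vmax: 4.343283582089551  # [uM/hr] FTS Vmax (formate folded in)
gamt.ki_sah: 16.0  # [uM] GAMT competitive Ki for SAH
gamt.km_sam: 49.0  # [uM] GAMT Km for SAM
gamt.vmax: 100.0  # [uM/hr] GAMT Vmax
gamt.vmax_cell: 90.01789893617023  # [uM/hr] GAMT Vmax with guanidinoacetate folded in
gnmt.hill: 2.0  # [-] GNMT Hill coefficient for SAM
gnmt.ki_sah: 35.0  # [uM] GNMT competitive Ki for SAH
gnmt.km_sam: 100.0  # [uM] GNMT Km for SAM (Hill)
gnmt.km_sam_cell: 20.0  # [uM] GNMT half-saturation for SAM in the cellular form
gnmt.total: 1.0  # [uM] total GNMT protein (free + singly + doubly bound)
gnmt.vmax: 4000.0  # [1/hr] GNMT catalytic prefactor per uM active enzyme
gnmt.vmax_cell: 705.6580992069469  # [1/hr] GNMT prefactor with glycine folded in
input.methionine: 50.0  # [uM/hr] constant methionine input to the liver
mati.inhib_amp: 0.8  # [-] MAT-I SAM-sensitive activity amplitude
mati.inhib_base: 0.23  # [-] MAT-I residual activity at saturating SAM
mati.inhib_rate: 0.0026  # [1/uM] MAT-I exponential SAM-inhibition rate
mati.km_met: 41.0  # [uM] MAT-I Km for methionine
mati.vmax: 250.7155931893211  # [uM/hr] MAT-I Vmax (low-Km isoform)
matiii.act_amp: 5.7  # [-] MAT-III SAM-activation amplitude
matiii.act_ks: 600.0  # [uM] MAT-III SAM-activation half constant
matiii.km1_base: 20000.0  # [uM] MAT-III first methionine constant, no SAM
matiii.km2: 21.1  # [uM] MAT-III second methionine constant
matiii.vmax: 15075.526246789334  # [uM/hr] MAT-III Vmax (high-Km isoform)
ms.km_5mthf: 25.0  # [uM] MS Km for 5mTHF
ms.km_hcy: 0.1  # [uM] MS Km for Hcy
ms.vmax: 140.07432788505088  # [uM/hr] MS Vmax (B12 folded in)
mtch.km_ch: 5.0  # [uM] MTCH Km for CH=THF
mtch.km_f10: 20.0  # [uM] MTCH Km for 10f-THF (reverse)
mtch.vmax_f: 213.9130434782609  # [uM/hr] MTCH forward Vmax (CH=THF -> 10f-THF)
mtch.vmax_r: 178.14814814814818  # [uM/hr] MTCH reverse Vmax
mtd.km_ch: 20.0  # [uM] MTD Km for CH=THF (reverse)
mtd.km_ch2: 2.0  # [uM] MTD Km for CH2-THF
mtd.vmax_f: 125.10638297872342  # [uM/hr] MTD forward Vmax (CH2-THF -> CH=THF)
mtd.vmax_r: 551.7391304347826  # [uM/hr] MTD reverse Vmax
mthfr.hill: 2.0  # [-] MTHFR Hill coefficient for SAM inhibition
mthfr.ki_sam: 15.5  # [uM] MTHFR allosteric inhibition constant for SAM
mthfr.km_ch2: 50.0  # [uM] MTHFR Km for CH2-THF
mthfr.vmax: 4346.659952478136  # [uM/hr] MTHFR Vmax (NADPH folded in)
ne.k_f: 0.3283582089552239  # [1/hr] nonenzymatic THF + HCHO -> CH2-THF (HCHO folded)
ne.k_r: 1.6489361702127663  # [1/hr] nonenzymatic CH2-THF -> THF + HCHO
pemt.ki_sah: 3.8  # [uM] PEMT noncompetitive Ki for SAH
pemt.km_sam: 18.2  # [uM] PEMT Km for SAM
pemt.vmax: 250.0  # [uM/hr] PEMT Vmax
pemt.vmax_cell: 98.01318939244231  # [uM/hr] PEMT Vmax with phosphatidylethanolamine folded in
pgt.km_f10: 5.0  # [uM] PGT Km for 10f-THF
pgt.vmax: 3.351851851851852  # [uM/hr] PGT Vmax (GAR folded in)
sahh.km_hcy: 150.0  # [uM] SAHH Km for Hcy
sahh.km_sah: 6.5  # [uM] SAHH Km for SAH
sahh.vmax_f: 448.1375683887857  # [uM/hr] SAHH forward Vmax (SAH -> Hcy)
sahh.vmax_r: 4530.0  # [uM/hr] SAHH reverse Vmax (Hcy -> SAH, adenosine folded)
shmt.km_ch2: 10.0  # [uM] SHMT Km for CH2-THF (reverse)
shmt.km_thf: 50.0  # [uM] SHMT Km for THF
shmt.vmax_f: 372.3582089552239  # [uM/hr] SHMT forward Vmax (serine folded in)
shmt.vmax_r: 116.38297872340425  # [uM/hr] SHMT reverse Vmax (glycine folded in)
ts.km_ch2: 14.0  # [uM] TS Km for CH2-THF
ts.vmax: 15.893617021276594  # [uM/hr] TS Vmax (dUMP folded in)
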
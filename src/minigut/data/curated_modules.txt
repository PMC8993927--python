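# Curated-module fixtures for a fibre-to-SCFA minimal consortium.
# KO contents are ILLUSTRATIVE PLACEHOLDERS exercising the module grammar
# (steps, comma-separated alternatives, '+'-joined complexes); they are not
# a vetted reference annotation.
MF_CELLO	cellobiose degradation
K02759+K02760+K02761
K00702,K01223
///
MF_LACT_BIF	lactate consumption (electron bifurcation)
K00016,K03778
K03521+K03522
///
MF_12PD_I	1,2-propanediol production I (lactaldehyde route)
K08969
K00048
///
MF_12PD_II	1,2-propanediol production II (hydroxyacetone route)
K08969
K00002,K13979
///
MF_PROP_IV	propionate production IV (via 1,2-propanediol)
K01699+K13919+K13920
K13922
K00925
///
MF_BUT_PROXY	acetyl-CoA to crotonyl-CoA (butyrate-production proxy)
K00626
K00074
K01692,K01715
///
MF_FRUCTAN	fructan (inulin) degradation
K01193
K00847
///
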
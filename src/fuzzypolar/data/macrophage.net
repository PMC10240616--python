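# Macrophage polarization transcriptional regulatory network
# 29 nodes, 60 signed interactions: 15 extracellular inputs, 14 internal
# (transcription-factor and secreted-cytokine) nodes.
#
# RECONSTRUCTED rule set: the published model distributes the full rule list
# through supplementary material; this file rebuilds it from the mechanisms
# described in the accompanying text (STAT6 silencing NFkB/STAT1 through
# SOCS1; TGFB activating HIF1a while inactivating STAT1; glucocorticoids
# plus immune complexes driving ERK; adenosine/TLR4/hypoxia driving HIF1a;
# IL-6's anti-TNF action; autocrine TNFA maintenance of the M1 state) and is
# calibrated against the printed dose-response thresholds for interferon and
# IL-6. Nodes LPS and IL13 complete the extracellular inventory and are part
# of the reconstruction. Treat rules as data: every pipeline stage accepts
# any conforming network file.
#
# Format: <name>, <klass>, <rule-or-dash>   (klass: extracellular | tf)
#
# --- extracellular inputs (clamp-only) ---
IFNG, extracellular, -
IFNB, extracellular, -
TNFAe, extracellular, -
IL1B, extracellular, -
IL6e, extracellular, -
IL10e, extracellular, -
IL4e, extracellular, -
IL13, extracellular, -
IgG, extracellular, -
LPS, extracellular, -
GCGCR, extracellular, -
MCSF, extracellular, -
TGFB, extracellular, -
A2a, extracellular, -
Hypoxia, extracellular, -
# --- internal nodes ---
STAT1, tf, (IFNG OR IFNB) AND NOT (SOCS1 OR TGFB OR STAT3 OR HIF1a)
NFkB, tf, (TNFAe OR IL1B OR LPS OR IL6e OR AP1 OR TNFA) AND NOT (SOCS1 OR SOCS3 OR GCGCR OR TGFB OR IL10)
AP1, tf, IL6e OR (IgG AND GCGCR)
ERK, tf, IgG OR (IL1B AND TNFA)
STAT6, tf, (IL4e OR IL13 OR TGFB) AND NOT (STAT1 OR NFkB)
STAT3, tf, IL10e OR IL10 OR MCSF OR (IL6e AND IL10)
SOCS1, tf, STAT6 OR IL10
SOCS3, tf, STAT3
HIF1a, tf, (Hypoxia OR A2a OR LPS OR TGFB OR STAT3) AND NOT (STAT1 OR NFkB)
IL10, tf, (STAT6 AND IL4e) OR STAT3
TNFA, tf, (NFkB OR IL1B) AND NOT (IL6e OR STAT6 OR STAT3)
IL12, tf, (STAT1 OR NFkB) AND NOT (STAT3 OR STAT6)
IL6, tf, (NFkB OR ERK) AND NOT (STAT3 OR GCGCR)
VEGF, tf, HIF1a OR STAT3
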
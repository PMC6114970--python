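"""Canonical analyte roster for the 186-analyte targeted plasma panel.

The panel quantifies, in μmol/L of plasma: 40 acylcarnitines, 21 amino
acids, 19 biogenic amines, the summed hexoses channel, 76
phosphatidylcholines (38 diacyl + 38 acyl-alkyl), 14
lyso-phosphatidylcholines and 15 sphingomyelins.  An optional "energy"
extension adds lactate, the combined pyruvate/oxaloacetate channel,
alpha-ketoglutarate, fumarate and succinate.
"""

ACYLCARNITINES = (
    "C0", "C2", "C3", "C3:1", "C3-OH",
    "C4", "C4:1", "C4-OH",
    "C5", "C5:1", "C5:1-DC", "C5-DC", "C5-M-DC", "C5-OH",
    "C6", "C6:1", "C7-DC", "C8", "C9",
    "C10", "C10:1", "C10:2",
    "C12", "C12:1", "C12-DC",
    "C14", "C14:1", "C14:1-OH", "C14:2", "C14:2-OH",
    "C16", "C16:1", "C16:1-OH", "C16:2", "C16:2-OH", "C16-OH",
    "C18", "C18:1", "C18:1-OH", "C18:2",
)

AMINO_ACIDS = (
    "Ala", "Arg", "Asn", "Asp", "Cit", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Orn", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr",
    "Val",
)

BIOGENIC_AMINES = (
    "Ac-Orn", "ADMA", "alpha-AAA", "Carnosine", "Creatinine", "Histamine",
    "Kynurenine", "Met-SO", "Nitro-Tyr", "OH-Pro", "PEA", "Putrescine",
    "Sarcosine", "SDMA", "Serotonin", "Spermidine", "Spermine", "Taurine",
    "Total DMA",
)

HEXOSES = ("Hexoses",)

PC_AA = tuple(
    f"PC aa C{c}:{d}"
    for c, d in (
        (24, 0), (26, 0), (28, 1), (30, 0), (30, 2),
        (32, 0), (32, 1), (32, 2), (32, 3),
        (34, 1), (34, 2), (34, 3), (34, 4),
        (36, 0), (36, 1), (36, 2), (36, 3), (36, 4), (36, 5), (36, 6),
        (38, 0), (38, 1), (38, 3), (38, 4), (38, 5), (38, 6),
        (40, 1), (40, 2), (40, 3), (40, 4), (40, 5), (40, 6),
        (42, 0), (42, 1), (42, 2), (42, 4), (42, 5), (42, 6),
    )
)

PC_AE = tuple(
    f"PC ae C{c}:{d}"
    for c, d in (
        (30, 0), (30, 2),
        (32, 1), (32, 2), (32, 3),
        (34, 0), (34, 1), (34, 2), (34, 3),
        (36, 0), (36, 1), (36, 2), (36, 3), (36, 4), (36, 5),
        (38, 0), (38, 1), (38, 2), (38, 3), (38, 4), (38, 5), (38, 6),
        (40, 1), (40, 2), (40, 3), (40, 4), (40, 5), (40, 6),
        (42, 0), (42, 1), (42, 2), (42, 3), (42, 4), (42, 5),
        (44, 3), (44, 4), (44, 5), (44, 6),
    )
)

LYSO_PC = tuple(
    f"lysoPC a C{c}:{d}"
    for c, d in (
        (14, 0), (16, 0), (16, 1), (17, 0), (18, 0), (18, 1), (18, 2),
        (20, 3), (20, 4), (24, 0), (26, 0), (26, 1), (28, 0), (28, 1),
    )
)

SM = (
    "SM (OH) C14:1", "SM (OH) C16:1", "SM (OH) C22:1", "SM (OH) C22:2",
    "SM (OH) C24:1",
    "SM C16:0", "SM C16:1", "SM C18:0", "SM C18:1", "SM C20:2",
    "SM C22:3", "SM C24:0", "SM C24:1", "SM C26:0", "SM C26:1",
)

ENERGY = ("Lac", "Pyr", "alpha-KG", "Fum", "Suc")

CORE_PANEL = (
    ACYLCARNITINES + AMINO_ACIDS + BIOGENIC_AMINES + HEXOSES
    + PC_AA + PC_AE + LYSO_PC + SM
)

CLASS_OF = {}
for _names, _cls in (
    (ACYLCARNITINES, "acylcarnitine"),
    (AMINO_ACIDS, "amino_acid"),
    (BIOGENIC_AMINES, "biogenic_amine"),
    (HEXOSES, "hexoses"),
    (PC_AA, "PC_aa"),
    (PC_AE, "PC_ae"),
    (LYSO_PC, "lysoPC"),
    (SM, "SM"),
    (ENERGY, "energy"),
):
    for _n in _names:
        CLASS_OF[_n] = _cls

# The nine-essential convention; Cit and Orn are urea-cycle intermediates
# counted with the non-essential pool.
ESSENTIAL_AA = ("His", "Ile", "Leu", "Lys", "Met", "Phe", "Thr", "Trp", "Val")
NON_ESSENTIAL_AA = tuple(a for a in AMINO_ACIDS if a not in ESSENTIAL_AA)
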
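"""Declarative catalog of the panel's metabolite sums, ratios and
composite discriminant equations.

Each definition is an expression tree over analyte symbols with two
operators (sum, divide).  Evaluation is exact arithmetic: a missing
leaf or a zero denominator yields a missing value with a recorded
reason, never an infinity or an exception.

The catalog covers amino-acid and acylcarnitine sums, structural-lipid
sums, desaturase/elongase proxies, liver-function quotients (Fischer),
inborn-error-of-metabolism screening ratios, fatty-acid-oxidation and
CPT-2 deficiency ratios, oxidative-stress and arginine-methylation
markers, glutaminolysis/MYC-activity proxies, glycolysis proxies,
glycolysis–glutaminolysis balance equations, hexose composites, the
SFA/MUFA desaturation discriminant and the two-feature breast-cancer
signature equation.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np
import pandas as pd

from . import _roster
from .nomenclature import parse_metabolite_name
from .panel import PanelSchema, SampleTable, default_schema

__all__ = [
    "Leaf", "SumExpr", "DivExpr",
    "RatioDefinition", "RatioCatalog", "FeatureTable",
    "build_default_catalog", "evaluate_expression", "evaluate_catalog",
    "bc_signature", "concentration_degree",
]


# ---------------------------------------------------------------- AST

@dataclass(frozen=True)
class Leaf:
    name: str


@dataclass(frozen=True)
class SumExpr:
    terms: tuple


@dataclass(frozen=True)
class DivExpr:
    num: "Expr"
    den: "Expr"


Expr = Union[Leaf, SumExpr, DivExpr]


def _leaves(expr: Expr) -> set[str]:
    if isinstance(expr, Leaf):
        return {expr.name}
    if isinstance(expr, SumExpr):
        return set().union(*(_leaves(t) for t in expr.terms))
    return _leaves(expr.num) | _leaves(expr.den)


def concentration_degree(expr: Expr) -> int:
    """Net power of concentration carried by an expression: leaves have
    degree 1, sums preserve degree, division subtracts.  Pure ratios
    (degree 0) are invariant to global rescaling of all concentrations."""
    if isinstance(expr, Leaf):
        return 1
    if isinstance(expr, SumExpr):
        degs = {concentration_degree(t) for t in expr.terms}
        if len(degs) != 1:
            raise ValueError("sum of terms with mixed concentration degree")
        return degs.pop()
    return concentration_degree(expr.num) - concentration_degree(expr.den)


def expr_to_str(expr: Expr) -> str:
    if isinstance(expr, Leaf):
        return expr.name
    if isinstance(expr, SumExpr):
        return "(" + " + ".join(expr_to_str(t) for t in expr.terms) + ")"
    return f"({expr_to_str(expr.num)} / {expr_to_str(expr.den)})"


def _expr_to_json(expr: Expr):
    if isinstance(expr, Leaf):
        return expr.name
    if isinstance(expr, SumExpr):
        return {"sum": [_expr_to_json(t) for t in expr.terms]}
    return {"div": [_expr_to_json(expr.num), _expr_to_json(expr.den)]}


def _expr_from_json(obj) -> Expr:
    if isinstance(obj, str):
        return Leaf(obj)
    if "sum" in obj:
        return SumExpr(tuple(_expr_from_json(t) for t in obj["sum"]))
    return DivExpr(_expr_from_json(obj["div"][0]), _expr_from_json(obj["div"][1]))


# ------------------------------------------------------------ catalog

@dataclass(frozen=True)
class RatioDefinition:
    name: str
    expression: Expr
    category: str
    direction_in_case: str = "unknown"  # up | down | unknown
    anchor: str = ""

    @property
    def leaves(self) -> set[str]:
        return _leaves(self.expression)

    def available_in(self, schema: PanelSchema) -> bool:
        return all(leaf in schema for leaf in self.leaves)


@dataclass
class RatioCatalog:
    definitions: list[RatioDefinition]
    unavailable: list[str] = field(default_factory=list)

    def __post_init__(self):
        names = [d.name for d in self.definitions]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate ratio names: {dup}")

    def __len__(self):
        return len(self.definitions)

    def __getitem__(self, name: str) -> RatioDefinition:
        for d in self.definitions:
            if d.name == name:
                return d
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(d.name == name for d in self.definitions)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.definitions]

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "name": d.name,
                    "expression": _expr_to_json(d.expression),
                    "category": d.category,
                    "direction_in_case": d.direction_in_case,
                    "anchor": d.anchor,
                }
                for d in self.definitions
            ],
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "RatioCatalog":
        return cls([
            RatioDefinition(
                name=e["name"],
                expression=_expr_from_json(e["expression"]),
                category=e["category"],
                direction_in_case=e.get("direction_in_case", "unknown"),
                anchor=e.get("anchor", ""),
            )
            for e in json.loads(text)
        ])

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class FeatureTable:
    """Sample × feature matrix produced from a catalog (NaN = missing)."""

    values: pd.DataFrame
    provenance: str = ""

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------- catalog builder

def _L(name: str) -> Leaf:
    return Leaf(name)


def _S(*items) -> SumExpr:
    return SumExpr(tuple(i if not isinstance(i, str) else Leaf(i) for i in items))


def _D(num, den) -> DivExpr:
    num = Leaf(num) if isinstance(num, str) else num
    den = Leaf(den) if isinstance(den, str) else den
    return DivExpr(num, den)


def _pc_ae_selection(min_carbons_exclusive: int, double_bonds: int) -> list[str]:
    """Acyl-alkyl PCs with more than `min_carbons_exclusive` carbons and
    the given unsaturation, derived mechanically from the name parser."""
    out = []
    for name in _roster.PC_AE:
        p = parse_metabolite_name(name)
        if p.carbons > min_carbons_exclusive and p.double_bonds == double_bonds:
            out.append(name)
    return out


def _dc_acylcarnitines() -> list[str]:
    return [
        n for n in _roster.ACYLCARNITINES
        if parse_metabolite_name(n).dicarboxyl
    ]


GLN_GLU = _D("Gln", "Glu")
GLN_GLU_ASP = _D(GLN_GLU, "Asp")           # [(Gln/Glu)/Asp]
SER_C2 = _D("Ser", "C2")                   # first-listed PHGDH proxy
CPT2 = _D(_S("C16", "C18:1"), "C2")
GCKR_2 = _D("PC aa C32:2", "PC ae C34:2")


def _bc_signature_expr(variant: str) -> DivExpr:
    # {PC aa C36:6 / [(Val/Phe)/Tau]} / C10:2 ; the Xle variant uses the
    # combined Leu+Ile signal (isobaric leucine/isoleucine).
    if variant == "val_phe":
        aa = _D("Val", "Phe")
    elif variant == "xle_phe":
        aa = _D(_S("Leu", "Ile"), "Phe")
    else:
        raise ValueError(f"unknown signature variant {variant!r}")
    return _D(_D("PC aa C36:6", _D(aa, "Taurine")), "C10:2")


def build_default_catalog(
    schema: PanelSchema | None = None, include_raw_markers: bool = True
) -> RatioCatalog:
    """Assemble the full default catalog against a schema.

    Entries whose leaves are absent from the schema (e.g. the energy
    channels when the extension is off) are kept but listed in
    ``catalog.unavailable``; they evaluate to missing.
    """
    if schema is None:
        schema = default_schema()

    defs: list[RatioDefinition] = []

    def add(name, expr, category, direction="unknown", anchor=""):
        defs.append(RatioDefinition(name, expr, category, direction, anchor))

    # --- amino-acid sums
    add("Essential AA", _S(*_roster.ESSENTIAL_AA), "aa_sum")
    add("non-Essential AA", _S(*_roster.NON_ESSENTIAL_AA), "aa_sum")
    add("Gluc AA", _S("Ala", "Gly", "Ser"), "aa_sum")
    add("BCAA", _S("Leu", "Ile", "Val"), "aa_sum")
    add("Arom AA", _S("His", "Tyr", "Trp", "Phe"), "aa_sum")
    add("Ala+Asp+Glu", _S("Ala", "Asp", "Glu"), "aa_sum", "up")
    add("Total AA", _S(*_roster.AMINO_ACIDS), "aa_sum")

    # --- acylcarnitine sums
    add("Total AC", _S(*_roster.ACYLCARNITINES), "ac_sum")
    add("C2+C3", _S("C2", "C3"), "ac_sum")
    add("C16+C18", _S("C16", "C18"), "ac_sum", "up")
    add("C16+C18:1", _S("C16", "C18:1"), "ac_sum", "up")
    add("C16-OH+C18:1-OH", _S("C16-OH", "C18:1-OH"), "ac_sum")
    add("AcylC-DC", _S(*_dc_acylcarnitines()), "ac_sum")

    # --- structural-lipid sums
    add("Total LPC", _S(*_roster.LYSO_PC), "lipid_sum")
    add("Total PC aa", _S(*_roster.PC_AA), "lipid_sum")
    add("Total PC ae", _S(*_roster.PC_AE), "lipid_sum")
    add("Total SM", _S(*_roster.SM), "lipid_sum")
    add("Structural lipids",
        _S(*(_roster.LYSO_PC + _roster.PC_AA + _roster.PC_AE + _roster.SM)),
        "lipid_sum")

    # --- desaturase / elongase proxies on ether lipids
    add("Desaturase 9",
        _D(_S("PC ae C36:1", "PC ae C38:1", "PC ae C42:1"), "PC ae C42:0"),
        "desaturase")
    add("Desaturase 6",
        _D(_S("PC ae C44:6", "PC ae C44:5", "PC ae C42:5", "PC ae C40:6",
              "PC ae C40:5", "PC ae C38:6", "PC ae C38:5", "PC ae C36:5"),
           _S("PC ae C36:1", "PC ae C38:1", "PC ae C42:1")),
        "desaturase")
    add("ELOVL2", _D("PC aa C40:3", "PC aa C42:5"), "desaturase")

    # --- liver function (Fischer's quotient and variants)
    add("Fischer", _D(_S("Leu", "Ile", "Val"), _S("Tyr", "Phe")),
        "liver", "down")
    add("Val/Phe", _D("Val", "Phe"), "liver", "down")
    add("Xle/Phe", _D(_S("Leu", "Ile"), "Phe"), "liver", "down")

    # --- classical IEM screening ratios
    add("C5/C4", _D("C5", "C4"), "iem")          # isovaleric acidemia
    add("Tyr/Ser", _D("Tyr", "Ser"), "iem")      # tyrosinemia
    add("Gly/Ala", _D("Gly", "Ala"), "iem")      # urea-cycle
    add("Gly/Gln", _D("Gly", "Gln"), "iem")
    add("Lac/Pyr", _D("Lac", "Pyr"), "iem", "up")  # OxPhos deficiency

    # --- FAOD / VLCAD / CPT-2 proxies
    add("CPT2", CPT2, "faod")
    add("C14:1/C4", _D("C14:1", "C4"), "faod")
    add("C14:1-OH/C9", _D("C14:1-OH", "C9"), "faod")
    add("C14/C9", _D("C14", "C9"), "faod")
    add("C14:1/C9", _D("C14:1", "C9"), "faod")
    add("C16/C3", _D("C16", "C3"), "faod")
    add("C18:1/C8", _D("C18:1", "C8"), "faod")

    # --- oxidative-stress and arginine-methylation markers
    if include_raw_markers:
        add("Met-SO", _L("Met-SO"), "oncometabolite", "up")
        add("ADMA", _L("ADMA"), "myc_proxy")
        add("SDMA", _L("SDMA"), "myc_proxy")
        add("Total DMA", _L("Total DMA"), "myc_proxy", "up")
    add("Met-SO/Met", _D("Met-SO", "Met"), "oncometabolite", "up")
    add("ADMA/Arg", _D("ADMA", "Arg"), "myc_proxy")
    add("SDMA/Arg", _D("SDMA", "Arg"), "myc_proxy")
    add("Total DMA/Arg", _D("Total DMA", "Arg"), "myc_proxy")
    add("Total DMA/[(Gln/Glu)/Asp]", _D("Total DMA", GLN_GLU_ASP),
        "myc_proxy", "up")
    add("Tau/[(Gln/Glu)/Asp]", _D("Taurine", GLN_GLU_ASP), "myc_proxy", "up")

    # --- glutaminolysis / MYC proxies
    add("Gln/Glu", GLN_GLU, "myc_proxy", "down")
    add("(Glu+Asp+Ala)/Gln", _D(_S("Glu", "Asp", "Ala"), "Gln"),
        "myc_proxy", "up")
    add("(Gln/Glu)/Asp", GLN_GLU_ASP, "myc_proxy", "down")
    add("Glu/Hexoses", _D("Glu", "Hexoses"), "myc_proxy", "up")
    # murine "Glucose" ratios map onto the hexoses channel
    add("Hexoses/Ser", _D("Hexoses", "Ser"), "myc_proxy")
    add("Hexoses/Gly", _D("Hexoses", "Gly"), "myc_proxy")
    add("Hexoses/Ala", _D("Hexoses", "Ala"), "myc_proxy")
    # ornithine-decarboxylase panel
    if include_raw_markers:
        add("Glu", _L("Glu"), "myc_proxy", "up")
        add("Pro", _L("Pro"), "myc_proxy")
        add("Orn", _L("Orn"), "myc_proxy")
        add("Putrescine", _L("Putrescine"), "myc_proxy")
        add("Spermidine", _L("Spermidine"), "myc_proxy")
        add("Spermine", _L("Spermine"), "myc_proxy")
    add("Glu/Orn", _D("Glu", "Orn"), "myc_proxy")
    add("Pro/Orn", _D("Pro", "Orn"), "myc_proxy")
    add("Orn/Arg", _D("Orn", "Arg"), "myc_proxy")
    add("Putrescine/Orn", _D("Putrescine", "Orn"), "myc_proxy")
    add("Spermidine/Putrescine", _D("Spermidine", "Putrescine"), "myc_proxy")
    add("Spermine/Spermidine", _D("Spermine", "Spermidine"), "myc_proxy")
    # transaminase proxies
    add("ALT", _D("Ala", "Glu"), "liver", "down")
    add("AST", _D("Asp", "Glu"), "liver")
    # glutamate pulling-effect composites
    add("(Glu/Hexoses)/(Ala/Glu)",
        _D(_D("Glu", "Hexoses"), _D("Ala", "Glu")), "myc_proxy", "up")
    add("[(Glu/Gln)/Hexoses]/(Ala/Glu)",
        _D(_D(_D("Glu", "Gln"), "Hexoses"), _D("Ala", "Glu")),
        "myc_proxy", "up")

    # --- glycolysis proxies (PHGDH, GCKR)
    add("Ser/C2", SER_C2, "glycolysis")
    add("Ser/Gln", _D("Ser", "Gln"), "glycolysis")
    add("Ser/Thr", _D("Ser", "Thr"), "glycolysis")
    add("GCKR 1", _D("PC aa C42:0", "PC ae C32:3"), "glycolysis")
    add("GCKR 2", GCKR_2, "glycolysis")

    # --- glycolysis/glutaminolysis balance equations
    add("(Ser/C2)/(Gln/Glu)", _D(SER_C2, GLN_GLU), "balance", "up")
    add("(Ser/C2)/[(Gln/Glu)/Asp]", _D(SER_C2, GLN_GLU_ASP), "balance", "up")
    add("(PC aa C32:2/PC ae C34:2)/(Gln/Glu)", _D(GCKR_2, GLN_GLU), "balance")
    add("(PC aa C32:2/PC ae C34:2)/[(Gln/Glu)/Asp]",
        _D(GCKR_2, GLN_GLU_ASP), "balance")

    # --- hexose composites and oncometabolite ratios
    add("Hexoses/Lac", _D("Hexoses", "Lac"), "oncometabolite", "down")
    add("Fum/Hexoses", _D("Fum", "Hexoses"), "oncometabolite", "up")
    add("Suc/Hexoses", _D("Suc", "Hexoses"), "oncometabolite", "up")
    add("Hexoses/(Ala+Gly+Ser)", _D("Hexoses", _S("Ala", "Gly", "Ser")),
        "oncometabolite", "down")
    add("Hexoses/(C14:1/C4)", _D("Hexoses", _D("C14:1", "C4")),
        "oncometabolite", "down")
    add("Hexoses/(C18:1/C8)", _D("Hexoses", _D("C18:1", "C8")),
        "oncometabolite", "down")
    add("Hexoses/(C16/C3)", _D("Hexoses", _D("C16", "C3")),
        "oncometabolite", "down")
    add("Hexoses/CPTII", _D("Hexoses", CPT2), "oncometabolite", "down")
    add("Hexoses/PHGDH", _D("Hexoses", SER_C2), "oncometabolite", "down")
    add("Hexoses/AcylC-DC", _D("Hexoses", _S(*_dc_acylcarnitines())),
        "oncometabolite", "down")
    add("Hexoses/lysoPC a C26:1", _D("Hexoses", "lysoPC a C26:1"),
        "oncometabolite", "down")
    add("Hexoses/lysoPC a C28:1", _D("Hexoses", "lysoPC a C28:1"),
        "oncometabolite", "down")

    # --- SFA/MUFA desaturation discriminant (acyl-alkyl PCs > 36 C)
    sfa = _pc_ae_selection(36, 0)
    mufa = _pc_ae_selection(36, 1)
    add("SFA", _S(*sfa), "lipid_sum")
    add("MUFA", _S(*mufa), "lipid_sum")
    # Asp rises and Gln falls in cases, so the Asp/Gln denominator
    # rises sharply and this discriminant falls in cases.
    add("(SFA/MUFA)/(Asp/Gln)",
        _D(_D(_S(*sfa), _S(*mufa)), _D("Asp", "Gln")),
        "discriminant", "down")

    # --- composite discriminants
    add("Phe/[(Gln/Glu)/Asp]", _D("Phe", GLN_GLU_ASP), "discriminant", "up")

    # --- the two-feature breast-cancer signature
    add("bc_signature", _bc_signature_expr("val_phe"), "discriminant", "up")
    add("bc_signature_xle", _bc_signature_expr("xle_phe"), "discriminant", "up")
    if include_raw_markers:
        add("PC aa C28:1", _L("PC aa C28:1"), "discriminant")

    unavailable = [d.name for d in defs if not d.available_in(schema)]
    return RatioCatalog(definitions=defs, unavailable=unavailable)


# --------------------------------------------------------- evaluation

def evaluate_expression(
    defn: RatioDefinition | Expr, sample: Mapping[str, float]
) -> tuple[float, str | None]:
    """Evaluate one definition on a single concentration map.

    Returns ``(value, None)`` or ``(nan, reason)`` where the reason
    names the missing leaf or the zero denominator.
    """
    expr = defn.expression if isinstance(defn, RatioDefinition) else defn

    def ev(e: Expr) -> tuple[float, str | None]:
        if isinstance(e, Leaf):
            v = sample.get(e.name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return math.nan, f"missing analyte {e.name}"
            return float(v), None
        if isinstance(e, SumExpr):
            total = 0.0
            for t in e.terms:
                v, r = ev(t)
                if r:
                    return math.nan, r
                total += v
            return total, None
        num, r = ev(e.num)
        if r:
            return math.nan, r
        den, r = ev(e.den)
        if r:
            return math.nan, r
        if den == 0.0:
            return math.nan, f"zero denominator {expr_to_str(e.den)}"
        return num / den, None

    return ev(expr)


def _evaluate_vectorized(expr: Expr, data: pd.DataFrame) -> pd.Series:
    if isinstance(expr, Leaf):
        if expr.name in data.columns:
            return data[expr.name].astype(float)
        return pd.Series(np.nan, index=data.index)
    if isinstance(expr, SumExpr):
        acc = _evaluate_vectorized(expr.terms[0], data)
        for t in expr.terms[1:]:
            acc = acc + _evaluate_vectorized(t, data)
        return acc
    num = _evaluate_vectorized(expr.num, data)
    den = _evaluate_vectorized(expr.den, data)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den.where(den != 0.0)
    return out.replace([np.inf, -np.inf], np.nan)


def evaluate_catalog(
    table: SampleTable,
    catalog: RatioCatalog | None = None,
    include_raw: bool = False,
) -> FeatureTable:
    """Evaluate every catalog entry over a SampleTable.

    One column per definition, order-stable and deterministic;
    missingness propagates per cell.  ``include_raw`` appends the raw
    analyte columns after the catalog features.
    """
    if catalog is None:
        catalog = build_default_catalog()
    cols = {
        d.name: _evaluate_vectorized(d.expression, table.data)
        for d in catalog.definitions
    }
    values = pd.DataFrame(cols, index=table.data.index)
    if include_raw:
        raw = table.data[[c for c in table.data.columns if c not in values]]
        values = pd.concat([values, raw], axis=1)
    return FeatureTable(values=values, provenance=catalog.content_hash())


def bc_signature(
    sample: Mapping[str, float], variant: str = "val_phe"
) -> tuple[float, float]:
    """The two-feature breast-cancer signature for one sample.

    Returns the equation value {PC aa C36:6 / [(Val/Phe)/Tau]} / C10:2
    (or the Xle/Phe variant, with Xle the combined Leu+Ile signal) and
    the raw PC aa C28:1 concentration; both feed the downstream
    bivariate classifier.  Net concentration degree of the equation is
    1: doubling every input doubles the score.
    """
    value, _reason = evaluate_expression(_bc_signature_expr(variant), sample)
    pc281 = sample.get("PC aa C28:1", math.nan)
    return value, float(pc281) if pc281 is not None else math.nan
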
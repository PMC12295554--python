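"""Deterministic toy metabolic networks with closed-form optima.

The generator emits a ~39-reaction fungal-style network that mirrors, in
miniature, the structure the cordycepin analyses assume:

* exchanges for glucose, ammonia and the essential nutrients (O2, phosphate,
  sulfate), plus CO2/water, cordycepin, biomass, and optional alternative
  substrates (D-glucosamine, L-aspartate, xylose, chitosan);
* lumped glycolysis and TCA with oxidative phosphorylation at a fixed P/O
  ratio (2.5 ATP per ½ O2 by default);
* an oxidative pentose-phosphate branch producing ribose-5-phosphate and
  NADPH, plus a reversible non-oxidative (transketolase-like) shunt;
* a one-carbon/folate branch (formate synthesis → formate–tetrahydrofolate
  ligase) feeding a lumped purine pathway that converts R5P + glycine +
  2 formyl-THF into adenosine, finished by two heterologous-style steps
  (adenosine → 3'-AMP → cordycepin) that carry EC numbers but no gene
  association, as in the engineered strain;
* an ATP maintenance reaction ``m_ATP`` and a biomass reaction whose
  growth-associated ATP cost (GAM) is a parameter.

Every internal reaction is elementally balanced on C, N, O, P and S
(hydrogen is not tracked).  The precursor demands of the biomass reaction
are chosen so that the network's optima have closed forms; the certificate
returned by :func:`toy_certificate` evaluates those forms with exact
rational arithmetic, giving an oracle that is fully independent of the LP
solver.  With the default parameters (reference glucose uptake 10, GAM 30,
P/O 2.5, maintenance 1):

* ATP yield per glucose fully oxidized: ``K_glc = 4 + 10·P/O = 29``;
* ATP cost per cordycepin exported (direct costs plus the opportunity cost
  of the carbon it diverts): ``K_cord = 53``;
* ATP cost per gram biomass: ``D = 259 + GAM = 289``;
* hence ``µ(U, v) = (29·U − 1 − 53·v)/289`` — exactly 1.0 h⁻¹ for the
  wild type at uptake 10, a maximum cordycepin flux of 289/53, and a
  growth/production trade-off slope of −53/289.

The module also provides random micro-LP instances (≤ 12 reactions) used to
cross-check the solver against exhaustive vertex enumeration, and loaders
for the published composition/kinetics/validation tables shipped as TSV
fixtures.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from fractions import Fraction as F

import numpy as np
import pandas as pd

from .biomass import register_biomass_gam
from .core import MetabolicModel, Metabolite, Reaction, parse_formula

# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------

ALL_SUBSTRATES = ("glucosamine", "aspartate", "xylose", "chitosan")
PLANTED_TARGETS = ("FTL", "FORSYN", "G6PPP")

#: biomass precursor demands, mmol per gDW (exact rationals)
ASP_PER_BIOMASS = F(23, 10)      # aspartate-family amino acid pool
CYS_PER_BIOMASS = F(11, 50)      # sulfur amino acid pool
GLYCEROL_PER_BIOMASS = F(1, 5)
R5P_PER_BIOMASS = F(1, 20)       # nucleic-acid proxy (keeps phosphate essential)

MAINTENANCE = F(1)               # m_ATP flux, mmol gDW⁻¹ h⁻¹
UPTAKE_REF = F(10)               # reference glucose uptake anchoring the yield
INTERNAL_BOUND = 1e6             # effectively unbounded internal flux

CHITOSAN_DP = 10  # degree of polymerization of the chitosan proxy


class ToyGenerationError(ValueError):
    pass


@dataclass(frozen=True)
class ToySpec:
    """Parameters of the generated toy network.

    ``glucose_yield`` (gDW per mmol glucose) anchors the wild-type growth at
    the reference uptake of 10: the glucan demand of the biomass reaction is
    derived so that µ = glucose_yield × 10 exactly.  ``seed`` only jitters
    non-binding internal upper bounds; stoichiometry is never randomized, so
    all certificate values stay exact.
    """

    glucose_yield: float = 0.1
    gam: float = 30.0
    po_ratio: float = 2.5
    cordycepin_branch: bool = True
    ppp_branch: bool = True
    alternative_substrates: tuple[str, ...] = ALL_SUBSTRATES
    planted_targets: tuple[str, ...] = PLANTED_TARGETS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.glucose_yield <= 0 or self.gam < 0:
            raise ToyGenerationError("glucose_yield must be > 0 and gam >= 0")
        if self.cordycepin_branch and not self.ppp_branch:
            raise ToyGenerationError(
                "cordycepin branch requires the pentose-phosphate branch "
                "(its R5P and NADPH supply)"
            )
        unknown = set(self.alternative_substrates) - set(ALL_SUBSTRATES)
        if unknown:
            raise ToyGenerationError(f"unknown alternative substrates: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# exact design algebra
# ---------------------------------------------------------------------------

def _design(spec: ToySpec) -> dict[str, F]:
    """Exact rational design constants for a spec (see module docstring)."""
    P = F(spec.po_ratio).limit_denominator(10**6)
    gam = F(spec.gam).limit_denominator(10**6)
    Y = F(spec.glucose_yield).limit_denominator(10**6)
    K_g6p = 5 + 10 * P          # ATP per G6P fully oxidized
    K_glc = K_g6p - 1           # ... per glucose (hexokinase cost)
    K_pyr = 1 + 4 * P           # ATP per pyruvate oxidized
    # ATP cost per cordycepin: 4 (purine assembly) + 2 (formate ligation)
    # + 1 (3'-phosphorylation) + opportunity cost of 7/6 G6P + 1 pyruvate
    K_cord = 7 + F(7, 6) * K_g6p + K_pyr
    b, b2, c, rho = ASP_PER_BIOMASS, CYS_PER_BIOMASS, GLYCEROL_PER_BIOMASS, R5P_PER_BIOMASS
    # target ATP cost per biomass so that µ = Y·U_ref at the reference uptake
    D = (K_glc * UPTAKE_REF - MAINTENANCE) / (Y * UPTAKE_REF)
    G6 = (D - (b + b2) * K_pyr - (b + 3 * b2) - (c + 4 * b2) * P - gam) / K_g6p
    glucan = G6 - c / 2 - F(5, 6) * rho
    if glucan <= 0:
        raise ToyGenerationError(
            "infeasible design: glucose_yield/GAM combination leaves no room "
            "for the structural carbohydrate demand"
        )
    return {
        "P": P, "gam": gam, "K_g6p": K_g6p, "K_glc": K_glc, "K_pyr": K_pyr,
        "K_cord": K_cord, "D": D, "G6": G6, "glucan": glucan,
        "b": b, "b2": b2, "c": c, "rho": rho,
        "N_bm": b + b2, "N_cord": F(5),
    }


def toy_certificate(spec: ToySpec | None = None) -> dict:
    """Analytic optima of the generated network, as plain floats.

    All values follow from the linear ATP/carbon/nitrogen accounting of the
    designed stoichiometry (derived symbolically with exact rationals), never
    from an LP solve.
    """
    spec = spec or ToySpec()
    d = _design(spec)
    U = UPTAKE_REF
    m = MAINTENANCE

    def mu(uptake: F, v_cord: F = F(0)) -> F:
        return (d["K_glc"] * uptake - m - d["K_cord"] * v_cord) / d["D"]

    mu_wt = mu(U)
    v_max = (d["K_glc"] * U - m) / d["K_cord"]
    producer_v = F(2)
    # internal-route feasibility of the closed forms at the certificate points
    for vv, muv in ((F(0), mu_wt), (v_max, F(0)), (producer_v, mu(U, producer_v))):
        v_emp = U - d["G6"] * muv - F(7, 6) * vv
        v_tca = 2 * v_emp - d["N_bm"] * muv - vv
        assert v_emp >= 0 and v_tca >= 0, "toy design violates its carbon routing"

    growth_fraction = F(9, 10)
    v_plateau = (1 - growth_fraction) * (d["K_glc"] * U - m) / d["K_cord"]
    ammonia_threshold = d["N_cord"] * v_plateau + d["N_bm"] * growth_fraction * mu_wt

    scan_fix = F(1, 4)
    scan_level = F(1000)
    # Only the xylose/C-limited point has a closed form: production is bound
    # by the 1 mmol ammonia budget, far below the O2/CO2 transport sentinels.
    # Points supplemented at the 1000-level saturate those sentinels and are
    # asserted qualitatively (source classification), not numerically.
    xyl_climited = (1 - d["N_bm"] * scan_fix) / d["N_cord"]

    cert = {
        "uptake_ref": float(U),
        "maintenance": float(m),
        "gam": float(d["gam"]),
        "po_ratio": float(d["P"]),
        "atp_per_glucose": float(d["K_glc"]),
        "atp_per_cordycepin": float(d["K_cord"]),
        "atp_per_biomass": float(d["D"]),
        "mu_max_wt": float(mu_wt),
        "cordycepin_max": float(v_max),
        "tradeoff_slope": float(-d["K_cord"] / d["D"]),
        "producer": {"cordycepin": float(producer_v), "mu": float(mu(U, producer_v))},
        "nitrogen_per_biomass": float(d["N_bm"]),
        "nitrogen_per_cordycepin": float(d["N_cord"]),
        "fseof": {
            "target_slopes": {"FTL": 2.0, "FORSYN": 2.0, "G6PPP": 2.0},
            "product_slope": 1.0,
        },
        "fba_candidates": ["G6PPP", "FORSYN", "FTL", "GLYSYN", "CORDSYN", "TKTL"],
        "target_genes": {
            "FTL": ["Ao_ftl1"],
            "FORSYN": ["Ao_fdh1", "Ao_fdh2"],
            "G6PPP": ["Ao_gnd1", "Ao_zwf1"],
        },
        "scan": {
            "growth_fix": float(scan_fix),
            "test_level": float(scan_level),
            "classes": {
                "EX_glcN": "dual_CN_sources",
                "EX_asp": "dual_CN_sources",
                "EX_chitosan": "dual_CN_sources",
                "EX_xyl": "C_sources",
            },
            "values": {
                "EX_xyl": {"C_limited": float(xyl_climited),
                           "CN_limited": 0.0, "N_limited": 0.0},
            },
        },
        "cn_opt": {
            "growth_fraction": float(growth_fraction),
            "glucose": float(U),
            "ammonia_threshold": float(ammonia_threshold),
            "ammonia_grid_optimum": 5.0,
            "ratio_optimum": float(6 * U / F(5)),
            "cordycepin": float(v_plateau),
        },
    }
    return cert


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

_MET_FORMULAS = {
    # extracellular
    "glc[e]": "C6O6", "nh3[e]": "N", "o2[e]": "O2", "pi[e]": "O4P",
    "so4[e]": "O4S", "co2[e]": "CO2", "h2o[e]": "O",
    "cordycepin[e]": "C10N5O3", "glcN[e]": "C6NO5", "asp[e]": "C4NO4",
    "xyl[e]": "C5O5", "chitosan[e]": "C60N10O41", "biomass[e]": "",
    # cytosolic
    "g6p[c]": "C6O9P", "pyr[c]": "C3O3",
    "atp[c]": "C10N5O13P3", "adp[c]": "C10N5O10P2",
    "nad[c]": "C21N7O14P2", "nadh[c]": "C21N7O14P2",
    "nadp[c]": "C21N7O17P3", "nadph[c]": "C21N7O17P3",
    "r5p[c]": "C5O8P", "glucan[c]": "C6O5", "asp[c]": "C4NO4",
    "cys[c]": "C3NO2S", "gly[c]": "C2NO2", "glyc[c]": "C3O3",
    "for[c]": "CO2", "thf[c]": "C19N7O6", "fthf[c]": "C20N7O7",
    "ado[c]": "C10N5O4", "amp3[c]": "C10N5O7P",
    "cordycepin[c]": "C10N5O3", "biomass[c]": "",
}

_MET_NAMES = {
    "glc[e]": "D-glucose", "nh3[e]": "ammonia", "o2[e]": "oxygen",
    "pi[e]": "phosphate", "so4[e]": "sulfate", "co2[e]": "carbon dioxide",
    "h2o[e]": "water", "cordycepin[e]": "cordycepin (3'-deoxyadenosine)",
    "glcN[e]": "D-glucosamine", "asp[e]": "L-aspartate", "xyl[e]": "D-xylose",
    "chitosan[e]": "chitosan (10-mer proxy)", "biomass[e]": "biomass",
    "g6p[c]": "glucose 6-phosphate", "pyr[c]": "pyruvate",
    "r5p[c]": "ribose 5-phosphate", "glucan[c]": "glucan monomer unit",
    "asp[c]": "L-aspartate", "cys[c]": "L-cysteine", "gly[c]": "glycine",
    "glyc[c]": "glycerol", "for[c]": "formate",
    "thf[c]": "tetrahydrofolate", "fthf[c]": "10-formyltetrahydrofolate",
    "ado[c]": "adenosine", "amp3[c]": "adenosine 3'-monophosphate",
    "cordycepin[c]": "cordycepin", "biomass[c]": "biomass",
}


def _rxn(id, eq, lb, ub, gpr="", ec=(), name=""):
    return (id, eq, lb, ub, gpr, list(ec), name)


def make_toy_model(spec: ToySpec | None = None) -> MetabolicModel:
    """Generate the toy network for a :class:`ToySpec` (see module docstring).

    The returned model validates, is elementally balanced on C/N/O/P/S for
    every internal reaction, declares the biomass reaction as its objective
    and registers the GAM term so :func:`cordyflux.fba.fit_gam` can
    re-parameterize it.
    """
    spec = spec or ToySpec()
    d = _design(spec)
    P = d["P"]
    gam = d["gam"]
    subs = set(spec.alternative_substrates)
    cord = spec.cordycepin_branch

    model = MetabolicModel(model_id="toy_oryzae", compartments={"c", "e"})
    model.annotations["toy_spec"] = spec
    model.annotations["certificate"] = toy_certificate(spec)

    used_mets = set(_MET_FORMULAS)
    if "xylose" not in subs:
        used_mets -= {"xyl[e]"}
    if "aspartate" not in subs:
        used_mets -= {"asp[e]"}
    if "chitosan" not in subs:
        used_mets -= {"chitosan[e]"}
    if "glucosamine" not in subs and "chitosan" not in subs:
        used_mets -= {"glcN[e]"}
    if not cord:
        used_mets -= {"for[c]", "thf[c]", "fthf[c]", "ado[c]", "amp3[c]",
                      "cordycepin[c]", "cordycepin[e]", "gly[c]"}
    if not spec.ppp_branch and not cord:
        pass  # r5p stays: it is a biomass precursor

    for mid in _MET_FORMULAS:
        if mid not in used_mets:
            continue
        formula = parse_formula(_MET_FORMULAS[mid]) if _MET_FORMULAS[mid] else None
        model.add_metabolite(
            Metabolite(id=mid, name=_MET_NAMES.get(mid, mid),
                       compartment=mid[mid.index("[") + 1], formula=formula)
        )

    fnum = lambda x: repr(float(x))  # noqa: E731 - exact decimal via repr
    reactions: list[tuple] = []

    # exchanges (uptake = negative flux; protocol constraints set regimes)
    for mid in ("glc", "nh3", "o2", "pi", "so4", "co2", "h2o"):
        reactions.append(_rxn(f"EX_{mid}", f"{mid}[e] <=>", -1000, 1000))
    reactions.append(_rxn("EX_biomass", "biomass[e] <=>", 0, 1000, name="biomass sink (bmOUT)"))
    if cord:
        reactions.append(_rxn("EX_cordycepin", "cordycepin[e] <=>", 0, 1000,
                              name="cordycepin sink (cordycepinOUT)"))
    if "glucosamine" in subs:
        reactions.append(_rxn("EX_glcN", "glcN[e] <=>", -1000, 1000))
    if "aspartate" in subs:
        reactions.append(_rxn("EX_asp", "asp[e] <=>", -1000, 1000))
    if "xylose" in subs:
        reactions.append(_rxn("EX_xyl", "xyl[e] <=>", -1000, 1000))
    if "chitosan" in subs:
        reactions.append(_rxn("EX_chitosan", "chitosan[e] <=>", -1000, 1000))

    B = INTERNAL_BOUND
    reactions += [
        _rxn("HEX", "glc[e] + atp[c] => g6p[c] + adp[c]", 0, B,
             gpr="Ao_hxk1", ec=["2.7.1.1"], name="hexokinase"),
        _rxn("EMP", "g6p[c] + 3 adp[c] + 2 pi[e] + 2 nad[c] => "
             "2 pyr[c] + 3 atp[c] + 2 nadh[c] + 2 h2o[e]", 0, B,
             gpr="Ao_pfk1", ec=["2.7.1.11"], name="glycolysis (lumped)"),
        _rxn("TCA", "pyr[c] + 4 nad[c] + adp[c] + pi[e] + 2 h2o[e] => "
             "3 co2[e] + 4 nadh[c] + atp[c]", 0, B,
             gpr="Ao_cit1", ec=["1.2.4.1"], name="pyruvate oxidation + TCA (lumped)"),
        _rxn("OXPHOS", f"nadh[c] + 0.5 o2[e] + {fnum(P)} adp[c] + {fnum(P)} pi[e] => "
             f"nad[c] + {fnum(P)} atp[c] + {fnum(P + 1)} h2o[e]", 0, B,
             gpr="Ao_cox1", ec=["7.1.1.2"],
             name=f"oxidative phosphorylation (P/O {float(P)})"),
        _rxn("PRECSYN", "g6p[c] => glucan[c] + pi[e]", 0, B,
             gpr="Ao_gsy1", ec=["2.4.1.34"], name="glucan synthase"),
        _rxn("ASPSYN", "pyr[c] + co2[e] + nh3[e] + atp[c] => asp[c] + adp[c] + pi[e]",
             0, B, gpr="Ao_aat2", ec=["2.6.1.1"], name="aspartate synthesis (lumped)"),
        _rxn("ASPDEG", "asp[c] + h2o[e] => pyr[c] + co2[e] + nh3[e]", 0, B,
             gpr="Ao_asp3", ec=["3.5.1.38"], name="aspartate degradation"),
        _rxn("CYSSYN", "pyr[c] + nh3[e] + so4[e] + 3 atp[c] + 4 nadh[c] => "
             "cys[c] + 3 adp[c] + 3 pi[e] + 4 nad[c] + 2 h2o[e]", 0, B,
             gpr="Ao_cys4", ec=["2.5.1.47"], name="cysteine synthesis (sulfate assimilation, lumped)"),
        _rxn("GLYCSYN", "g6p[c] + 2 nadh[c] + h2o[e] => 2 glyc[c] + 2 nad[c] + pi[e]",
             0, B, gpr="Ao_gpd1 Ao_gpp1", ec=["3.1.3.21"],
             name="glycerol branch (G3P dehydrogenase + phosphohydrolase)"),
        _rxn("GNG", "2 pyr[c] + 4 atp[c] + 2 nadh[c] + 3 h2o[e] => "
             "g6p[c] + 4 adp[c] + 3 pi[e] + 2 nad[c]", 0, B,
             gpr="Ao_fbp1", ec=["3.1.3.11"], name="gluconeogenesis (lumped)"),
        _rxn("m_ATP", "atp[c] + h2o[e] => adp[c] + pi[e]", 1, 1,
             name="ATP maintenance"),
        _rxn("BMt", "biomass[c] => biomass[e]", 0, B, name="biomass export"),
    ]
    if spec.ppp_branch:
        reactions += [
            _rxn("G6PPP", "g6p[c] + 2 nadp[c] + h2o[e] => r5p[c] + co2[e] + 2 nadph[c]",
                 0, B, gpr="Ao_zwf1 and Ao_gnd1", ec=["1.1.1.49"],
                 name="oxidative pentose phosphate pathway (lumped)"),
        ]
    reactions += [
        _rxn("TKTL", "6 r5p[c] + h2o[e] <=> 5 g6p[c] + pi[e]", -B, B,
             gpr="Ao_tkl1", ec=["2.2.1.1"], name="non-oxidative PPP shunt (lumped)"),
    ]
    if cord:
        reactions += [
            _rxn("GLYSYN", "pyr[c] + nh3[e] + h2o[e] => gly[c] + co2[e]", 0, B,
                 gpr="Ao_shm2", ec=["2.1.2.1"], name="glycine synthesis (lumped)"),
            _rxn("FORSYN", "co2[e] + nadph[c] => for[c] + nadp[c]", 0, B,
                 gpr="Ao_fdh1 Ao_fdh2", ec=["1.17.1.9"],
                 name="formate synthesis (one-carbon supply)"),
            _rxn("FTL", "for[c] + thf[c] + atp[c] => fthf[c] + adp[c] + pi[e]", 0, B,
                 gpr="Ao_ftl1", ec=["6.3.4.3"], name="formate-tetrahydrofolate ligase"),
            _rxn("CORDSYN", "r5p[c] + gly[c] + 2 fthf[c] + co2[e] + 4 nh3[e] + "
                 "4 atp[c] + 2 nadph[c] => ado[c] + 2 thf[c] + 4 adp[c] + 5 pi[e] + "
                 "2 nadp[c] + 2 h2o[e]", 0, B,
                 gpr="Ao_ade1 and Ao_ade2", ec=["6.3.4.13"],
                 name="purine pathway to adenosine (lumped)"),
            _rxn("CNS1", "ado[c] + atp[c] => amp3[c] + adp[c]", 0, B,
                 ec=["2.7.1.20"], name="adenosine 3'-kinase (heterologous, no annotated gene)"),
            _rxn("CNS2", "amp3[c] => cordycepin[c] + pi[e]", 0, B,
                 ec=["3.1.3.5"], name="3'-AMP phosphatase (heterologous, no annotated gene)"),
            _rxn("CORDt", "cordycepin[c] => cordycepin[e]", 0, B, name="cordycepin export"),
        ]
    if "aspartate" in subs:
        reactions.append(_rxn("ASPt", "asp[e] => asp[c]", 0, B, name="aspartate uptake transport"))
    if "xylose" in subs:
        reactions.append(_rxn("XYLA", "xyl[e] + atp[c] => r5p[c] + adp[c]", 0, B,
                              gpr="Ao_xks1", ec=["2.7.1.17"], name="xylose assimilation (lumped)"))
    if "glucosamine" in subs or "chitosan" in subs:
        reactions.append(_rxn("GLCNDEAM", "glcN[e] + atp[c] + h2o[e] => g6p[c] + nh3[e] + adp[c]",
                              0, B, gpr="Ao_nag1", ec=["3.5.99.6"],
                              name="glucosamine kinase + deaminase (lumped)"))
    if "chitosan" in subs:
        reactions.append(_rxn("CHITOHYD", f"chitosan[e] + {CHITOSAN_DP - 1} h2o[e] => "
                              f"{CHITOSAN_DP} glcN[e]", 0, B,
                              gpr="Ao_csn1", ec=["3.2.1.132"], name="chitosanase"))

    # biomass: precursor demands + GAM ATP cost, producing 1 g biomass per flux unit
    bm_parts = [
        f"{fnum(d['glucan'])} glucan[c]", f"{fnum(d['b'])} asp[c]",
        f"{fnum(d['b2'])} cys[c]", f"{fnum(d['rho'])} r5p[c]",
        f"{fnum(d['c'])} glyc[c]", f"{fnum(gam)} atp[c]", f"{fnum(gam)} h2o[e]",
    ]
    reactions.append(_rxn(
        "BIOMASS",
        " + ".join(bm_parts) + f" => biomass[c] + {fnum(gam)} adp[c] + {fnum(gam)} pi[e]",
        0, 1000, name="biomass synthesis"))

    from .core import parse_equation

    rng = np.random.default_rng(spec.seed)
    for rid, eq, lb, ub, gpr, ec, name in reactions:
        stoich, _ = parse_equation(eq)
        lb, ub = float(lb), float(ub)
        if spec.seed and ub == INTERNAL_BOUND and rid not in ("m_ATP", "BIOMASS"):
            ub += float(rng.uniform(0.0, 1e3))  # never binding: jitter only the sentinel
        rxn = Reaction(id=rid, name=name or rid, stoichiometry=stoich,
                       lower_bound=lb, upper_bound=ub, gpr=gpr, ec_numbers=ec)
        rxn.is_exchange = rid.startswith("EX_")
        model.add_reaction(rxn)

    model.objective_reaction_id = "BIOMASS"
    register_biomass_gam(model, "BIOMASS", float(gam),
                         currency={"atp": "atp[c]", "adp": "adp[c]",
                                   "h2o": "h2o[e]", "pi": "pi[e]"})
    missing_targets = set(spec.planted_targets) - set(model.reactions)
    if missing_targets:
        raise ToyGenerationError(f"planted targets not generated: {sorted(missing_targets)}")
    model.validate()
    bad = model.check_mass_balance()
    if bad:
        raise ToyGenerationError(f"internal reactions not elementally balanced: {bad}")
    return model


# ---------------------------------------------------------------------------
# random micro LP instances (solver oracle fodder)
# ---------------------------------------------------------------------------

def micro_lp_instances(count: int = 20, seed: int = 0) -> list[MetabolicModel]:
    """Random small stoichiometric models (≤ 12 reactions, finite bounds).

    Every instance is feasible (zero flux is always admissible) and bounded,
    so its optimum is attained at a vertex of the flux polytope and can be
    found by exhaustive vertex enumeration.  Used to cross-check the LP
    layer; the generation is fully determined by ``seed``.
    """
    rng = np.random.default_rng(seed)
    models = []
    for k in range(count):
        n_mets = int(rng.integers(2, 5))
        n_rxns = int(rng.integers(4, 11))
        model = MetabolicModel(model_id=f"micro_{k}", compartments={"c"})
        for i in range(n_mets):
            model.add_metabolite(Metabolite(id=f"m{i}[c]", compartment="c"))
        for j in range(n_rxns):
            n_part = int(rng.integers(1, min(3, n_mets) + 1))
            mets = rng.choice(n_mets, size=n_part, replace=False)
            coefs = rng.choice([-2, -1, 1, 2], size=n_part)
            stoich = {f"m{int(i)}[c]": float(cv) for i, cv in zip(mets, coefs)}
            lb = float(rng.choice([-10.0, 0.0]))
            ub = float(rng.choice([5.0, 10.0]))
            rxn = Reaction(id=f"r{j}", stoichiometry=stoich, lower_bound=lb, upper_bound=ub)
            model.reactions[rxn.id] = rxn  # skip exchange conventions on purpose
        model.objective_reaction_id = f"r{int(rng.integers(0, n_rxns))}"
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# published-table fixtures
# ---------------------------------------------------------------------------

@dataclass
class FixtureTables:
    """Machine-readable copies of the published composition/kinetics tables."""

    composition: pd.DataFrame
    kinetics: pd.DataFrame
    cn_validation: pd.DataFrame
    amplification_targets: pd.DataFrame
    amino_acids: pd.DataFrame

    def kinetic(self, parameter: str, strain: str) -> float:
        row = self.kinetics.set_index("parameter").loc[parameter]
        return float(row[strain])


def _data_path(name: str):
    return importlib.resources.files("cordyflux").joinpath("data", name)


def load_fixture_tables() -> FixtureTables:
    """Load the shipped TSV fixtures (biomass composition, strain kinetics,
    C:N validation titers, amplification-target gene table, amino acids)."""
    read = lambda n, **kw: pd.read_csv(_data_path(n), sep="\t", **kw)  # noqa: E731
    return FixtureTables(
        composition=read("biomass_composition.tsv"),
        kinetics=read("kinetics.tsv"),
        cn_validation=read("cn_validation.tsv"),
        amplification_targets=read("amplification_targets.tsv"),
        amino_acids=read("amino_acid_profile.tsv"),
    )
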
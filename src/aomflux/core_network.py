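"""Curated core model of nitrate-driven reverse methanogenesis.

The network oxidizes methane to CO2 through the reversed methanogenesis
pathway (Mcr, Mtr, Mer, Mtd, Mch, Ftr, Fmd), regenerates the CoM-S-S-CoB
heterodisulfide either through the cytoplasmic electron-confurcating HdrABC
(thiol pair + reduced-ferredoxin pair jointly reduce two F420) or the
membrane-bound HdrDE, and respires to nitrate through the menaquinone pool
(Fqo, Nar).  Ion translocation is explicit: outward-pumped protons and
sodium ions appear as extracellular species ``h_e``/``na_e`` that only
membrane enzymes produce or consume, and the ATP synthase consumes four
translocated ions per ATP.

Per methane fully oxidized, eight electrons leave as four redox pairs
(thiols via Mcr/Mtr, two F420 via Mer/Mtd, one ferredoxin pair via Fmd);
under confurcation all four pairs pass the F420 pool, so Fqo turns over
four times and Nar four times per methane, pumping 3 and 4 protons each.
At the reference uptake of 1.1 mmol gDW-1 h-1 this yields the ledger
13.2 (Fqo) + 17.6 (Nar) - 2.2 (Mtr, sodium inward) = 28.6 translocated
ions, i.e. 7.15 ATP at 4 ions/ATP.

Mechanistic variants probe the heterodisulfide reductase coupling:

``confurcation``
    the curated model itself (identity).
``R1``
    HdrABC without F420 coupling: 2 Fd_ox + CoM-SH + CoB-SH <=>
    2 Fd_red + 2 H+ + CoM-S-S-CoB.  Leaves the ferredoxin cycle without a
    net reoxidation route; the model cannot grow.
``R2``
    F420-driven heterodisulfide oxidation without ferredoxin:
    F420 + CoM-SH + CoB-SH <=> F420H2 + CoM-S-S-CoB.
``R3``
    R2 plus a hypothetical ferredoxin:F420 oxidoreductase
    (2 Fd_red + F420 + 2 H+ <=> 2 Fd_ox + F420H2), decoupling the two
    confurcation half-reactions.
``rnf_swap``
    HdrABC removed and a hypothetical sodium-pumping Rnf added
    (2 Fd_red + MQ -> 2 Fd_ox + MQH2, 4 Na+ outward); the Mrp antiporter
    is disabled so the ATP synthase draws only on the proton gradient.
``no_mrp`` / ``no_nrf``
    remove the Mrp antiporter / the Nrf nitrite reductase.
"""

from __future__ import annotations

from .defaults import default_parameters
from .model import (
    ModelError,
    Reaction,
    RedoxTransfer,
    Species,
    StoichiometricModel,
    Translocation,
)

__all__ = ["build_core_model", "apply_variant", "VARIANTS"]

VARIANTS = ("confurcation", "R1", "R2", "R3", "rnf_swap", "no_mrp", "no_nrf")

#: reaction ids with special roles
ATP_SYNTHASE_ID = "AtpSyn"
ATP_DEMAND_ID = "ATPM"
BIOMASS_ID = "Biomass"


def _species() -> list[Species]:
    c, e = "c", "e"
    return [
        Species("ch4_c", "methane", "CH4", 0, c),
        Species("co2_c", "carbon dioxide", "CO2", 0, c),
        Species("no3_c", "nitrate", "NO3", -1, c),
        Species("no2_c", "nitrite", "NO2", -1, c),
        Species("nh4_c", "ammonium", "NH4", 1, c),
        Species("h2o_c", "water", "H2O", 0, c),
        Species("h_c", "proton (cytoplasm)", "H", 1, c),
        Species("h_e", "proton (translocated)", "H", 1, e),
        Species("na_c", "sodium (cytoplasm)", "Na", 1, c),
        Species("na_e", "sodium (translocated)", "Na", 1, e),
        Species("pi_c", "phosphate", "HPO4", -2, c),
        Species("atp_c", "ATP", "C10H12N5O13P3", -4, c),
        Species("adp_c", "ADP", "C10H12N5O10P2", -3, c),
        Species("nadp_c", "NADP+", "Nd", 1, c),
        Species("nadph_c", "NADPH", "NdH", 0, c),
        Species("coa_c", "coenzyme A", "HCoa", 0, c),
        Species("accoa_c", "acetyl-CoA", "C2H3OCoa", 0, c),
        Species("fdox_c", "oxidized ferredoxin", "Fd", 0, c),
        Species("fdred_c", "reduced ferredoxin", "Fd", -1, c),
        Species("f420_c", "oxidized F420", "Ff", 0, c),
        Species("f420h2_c", "reduced F420 (F420H2)", "FfH2", 0, c),
        Species("mq_c", "menaquinone", "Mq", 0, c),
        Species("mqh2_c", "menaquinol", "MqH2", 0, c),
        Species("com_c", "CoM-SH", "HCm", 0, c),
        Species("cob_c", "CoB-SH", "HCb", 0, c),
        Species("hdsf_c", "CoM-S-S-CoB heterodisulfide", "CmCb", 0, c),
        Species("mcom_c", "methyl-CoM", "CH3Cm", 0, c),
        Species("h4mpt_c", "H4MPT", "H2Hm", 0, c),
        Species("ch3h4mpt_c", "methyl-H4MPT", "CH4Hm", 0, c),
        Species("ch2h4mpt_c", "methylene-H4MPT", "CH2Hm", 0, c),
        Species("chh4mpt_c", "methenyl-H4MPT+", "CHHm", 1, c),
        Species("formh4mpt_c", "formyl-H4MPT", "CH2OHm", 0, c),
        Species("mfr_c", "methanofuran", "HMf", 0, c),
        Species("formmfr_c", "formyl-MFR", "CHOMf", 0, c),
    ]


def build_core_model(parameters: dict | None = None) -> StoichiometricModel:
    """Build the curated core model with the confurcating HdrABC.

    ``parameters`` overrides entries of the packaged defaults (GAM, NGAM,
    reference methane uptake, ions per ATP, translocation counts, biomass
    composition).
    """
    params = default_parameters()
    if parameters:
        unknown = set(parameters) - set(params)
        if unknown:
            raise ModelError(f"unknown parameters: {sorted(unknown)}")
        params.update(parameters)

    inf = params["bound_inf"]
    gam = params["gam"]
    n_fqo = params["fqo_h_out"]
    n_nar = params["nar_h_out"]
    n_mtr = params["mtr_na_in"]
    n_hdrde = params["hdrde_h_in"]
    q = params["ions_per_atp"]
    b_ac = params["biomass_accoa"]
    b_nh = params["biomass_nadph"]

    rxns = [
        Reaction(
            "Mcr", "methyl-CoM reductase (reverse, methane activation)",
            {"ch4_c": -1, "hdsf_c": -1, "mcom_c": 1, "cob_c": 1},
            0, inf, "reverse methanogenesis",
            redox_transfers=(RedoxTransfer(2, "CH4", "CoM-CoB"),),
        ),
        Reaction(
            "Mtr", "methyl-H4MPT:CoM methyltransferase (reverse, 2 Na+ in)",
            {"mcom_c": -1, "h4mpt_c": -1, "na_e": -n_mtr,
             "ch3h4mpt_c": 1, "com_c": 1, "na_c": n_mtr},
            -inf, inf, "reverse methanogenesis",
            translocations=(Translocation("Na+", n_mtr, "inward"),),
        ),
        Reaction(
            "Mer", "methylene-H4MPT reductase (reverse, F420-reducing)",
            {"ch3h4mpt_c": -1, "f420_c": -1, "ch2h4mpt_c": 1, "f420h2_c": 1},
            -inf, inf, "reverse methanogenesis",
            redox_transfers=(RedoxTransfer(2, "C1", "F420"),),
        ),
        Reaction(
            "Mtd", "methylene-H4MPT dehydrogenase (reverse, F420-reducing)",
            {"ch2h4mpt_c": -1, "f420_c": -1, "h_c": -1, "chh4mpt_c": 1, "f420h2_c": 1},
            -inf, inf, "reverse methanogenesis",
            redox_transfers=(RedoxTransfer(2, "C1", "F420"),),
        ),
        Reaction(
            "Mch", "methenyl-H4MPT cyclohydrolase (reverse)",
            {"chh4mpt_c": -1, "h2o_c": -1, "formh4mpt_c": 1, "h_c": 1},
            -inf, inf, "reverse methanogenesis",
        ),
        Reaction(
            "Ftr", "formylmethanofuran:H4MPT formyltransferase (reverse)",
            {"formh4mpt_c": -1, "mfr_c": -1, "formmfr_c": 1, "h4mpt_c": 1},
            -inf, inf, "reverse methanogenesis",
        ),
        Reaction(
            "Fmd", "formylmethanofuran dehydrogenase (reverse, Fd-reducing)",
            {"formmfr_c": -1, "h2o_c": -1, "fdox_c": -2,
             "co2_c": 1, "mfr_c": 1, "fdred_c": 2, "h_c": 2},
            -inf, inf, "reverse methanogenesis",
            redox_transfers=(RedoxTransfer(2, "C1", "Fd"),),
        ),
        Reaction(
            "HdrABC", "electron-confurcating heterodisulfide reductase",
            {"com_c": -1, "cob_c": -1, "fdred_c": -2, "f420_c": -2, "h_c": -2,
             "hdsf_c": 1, "fdox_c": 2, "f420h2_c": 2},
            0, inf, "electron transport",
            redox_transfers=(
                RedoxTransfer(2, "CoM-CoB", "F420"),
                RedoxTransfer(2, "Fd", "F420"),
            ),
        ),
        Reaction(
            "HdrDE", "membrane heterodisulfide reductase (reverse, 2 H+ in)",
            {"com_c": -1, "cob_c": -1, "mq_c": -1, "h_e": -n_hdrde,
             "hdsf_c": 1, "mqh2_c": 1, "h_c": n_hdrde},
            0, inf, "electron transport",
            translocations=(Translocation("H+", n_hdrde, "inward"),),
            redox_transfers=(RedoxTransfer(2, "CoM-CoB", "MQ"),),
        ),
        Reaction(
            "Fqo", "F420H2:quinone oxidoreductase (3 H+ out)",
            {"f420h2_c": -1, "mq_c": -1, "h_c": -n_fqo,
             "f420_c": 1, "mqh2_c": 1, "h_e": n_fqo},
            0, inf, "electron transport",
            translocations=(Translocation("H+", n_fqo, "outward"),),
            redox_transfers=(RedoxTransfer(2, "F420", "MQ"),),
        ),
        Reaction(
            "Nar", "nitrate reductase / cytochrome complex (4 H+ out)",
            {"mqh2_c": -1, "no3_c": -1, "h_c": -n_nar,
             "mq_c": 1, "no2_c": 1, "h2o_c": 1, "h_e": n_nar},
            0, inf, "nitrate respiration",
            translocations=(Translocation("H+", n_nar, "outward"),),
            redox_transfers=(RedoxTransfer(2, "MQ", "NO3"),),
        ),
        Reaction(
            "Nrf", "nitrite reductase (menaquinol-coupled, to ammonium)",
            {"mqh2_c": -3, "no2_c": -1, "h_c": -2,
             "mq_c": 3, "nh4_c": 1, "h2o_c": 2},
            0, inf, "nitrate respiration",
            redox_transfers=(RedoxTransfer(6, "MQ", "NO2"),),
        ),
        Reaction(
            "Cdh", "CO dehydrogenase / acetyl-CoA synthase",
            {"ch3h4mpt_c": -1, "co2_c": -1, "fdred_c": -2, "coa_c": -1, "h_c": -2,
             "accoa_c": 1, "h4mpt_c": 1, "fdox_c": 2, "h2o_c": 1},
            0, inf, "acetyl-CoA synthesis",
            redox_transfers=(RedoxTransfer(2, "Fd", "C1"),),
        ),
        Reaction(
            "F4NR", "F420-dependent NADP reductase",
            {"f420h2_c": -1, "nadp_c": -1, "f420_c": 1, "nadph_c": 1, "h_c": 1},
            0, inf, "anabolic redox",
            redox_transfers=(RedoxTransfer(2, "F420", "NADP"),),
        ),
        Reaction(
            ATP_SYNTHASE_ID, f"ATP synthase ({q:g} translocated ions per ATP)",
            {"adp_c": -1, "pi_c": -1, "h_e": -q, "atp_c": 1, "h2o_c": 1, "h_c": q - 1},
            0, inf, "oxidative phosphorylation",
        ),
        Reaction(
            "Mrp", "Mrp Na+/H+ antiporter (1:1)",
            {"na_c": -1, "h_e": -1, "na_e": 1, "h_c": 1},
            -inf, inf, "ion homeostasis",
            translocations=(
                Translocation("Na+", 1, "outward"),
                Translocation("H+", 1, "inward"),
            ),
        ),
        Reaction(
            "NaLeak", "passive sodium uniport (gradient-dissipating)",
            {"na_e": -1, "na_c": 1},
            0, inf, "ion homeostasis",
        ),
        Reaction(
            ATP_DEMAND_ID, "ATP maintenance demand",
            {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
            params["ngam"], inf, "maintenance",
        ),
        Reaction(
            BIOMASS_ID, "lumped biomass drain",
            {"accoa_c": -b_ac, "nadph_c": -b_nh, "atp_c": -gam, "h2o_c": -gam,
             "coa_c": b_ac, "nadp_c": b_nh, "adp_c": gam, "pi_c": gam, "h_c": gam},
            0, inf, "biomass",
            lumped=True,
        ),
    ]

    # Exchange reactions (positive flux = export).  Methane uptake is bounded
    # by the reference uptake; nitrate is unconstrained.
    exchanges = [
        ("EX_ch4", "ch4_c", -params["ch4_uptake"], inf),
        ("EX_no3", "no3_c", -inf, inf),
        ("EX_no2", "no2_c", 0, inf),
        ("EX_nh4", "nh4_c", 0, inf),
        ("EX_co2", "co2_c", -inf, inf),
        ("EX_h2o", "h2o_c", -inf, inf),
        ("EX_h", "h_c", -inf, inf),
        ("EX_pi", "pi_c", -inf, inf),
    ]
    for rid, sid, lb, ub in exchanges:
        rxns.append(
            Reaction(rid, f"exchange of {sid}", {sid: -1}, lb, ub, "exchange")
        )

    model = StoichiometricModel(
        id="aom_core",
        species=_species(),
        reactions=rxns,
        objective_id=BIOMASS_ID,
        parameters=params,
    )
    model.check_structure()
    return model


def _pseudo_rnf(inf: float, n_na: float) -> Reaction:
    """Hypothetical Na+-pumping ferredoxin:menaquinone oxidoreductase."""
    return Reaction(
        "Rnf", "pseudo-Rnf (Fd:MQ oxidoreductase, 4 Na+ out)",
        {"fdred_c": -2, "mq_c": -1, "h_c": -2, "na_c": -n_na,
         "fdox_c": 2, "mqh2_c": 1, "na_e": n_na},
        0, inf, "electron transport",
        translocations=(Translocation("Na+", n_na, "outward"),),
        redox_transfers=(RedoxTransfer(2, "Fd", "MQ"),),
    )


def apply_variant(model: StoichiometricModel, variant_id: str) -> StoichiometricModel:
    """Return a new model with the requested mechanistic variant applied.

    The input model is never mutated.  See the module docstring for the
    meaning of each variant id.
    """
    if variant_id not in VARIANTS:
        raise ModelError(
            f"unknown variant '{variant_id}'; known variants: {', '.join(VARIANTS)}"
        )
    out = model.copy()
    inf = out.parameters.get("bound_inf", 1000.0)

    if variant_id == "confurcation":
        return out

    if variant_id == "R1":
        out.remove_reaction("HdrABC")
        out.reactions.append(Reaction(
            "R1", "Hdr without confurcation (Fd-reducing)",
            {"fdox_c": -2, "com_c": -1, "cob_c": -1,
             "fdred_c": 2, "h_c": 2, "hdsf_c": 1},
            -inf, inf, "electron transport",
            redox_transfers=(RedoxTransfer(2, "CoM-CoB", "Fd"),),
        ))
    elif variant_id in ("R2", "R3"):
        out.remove_reaction("HdrABC")
        out.reactions.append(Reaction(
            "R2", "F420-driven heterodisulfide oxidation",
            {"f420_c": -1, "com_c": -1, "cob_c": -1, "f420h2_c": 1, "hdsf_c": 1},
            -inf, inf, "electron transport",
            redox_transfers=(RedoxTransfer(2, "CoM-CoB", "F420"),),
        ))
        if variant_id == "R3":
            out.reactions.append(Reaction(
                "R3", "ferredoxin:F420 oxidoreductase (hypothetical)",
                {"fdred_c": -2, "f420_c": -1, "h_c": -2, "fdox_c": 2, "f420h2_c": 1},
                -inf, inf, "electron transport",
                redox_transfers=(RedoxTransfer(2, "Fd", "F420"),),
            ))
    elif variant_id == "rnf_swap":
        out.remove_reaction("HdrABC")
        n_na = out.parameters.get("rnf_na_out", 4)
        out.reactions.append(_pseudo_rnf(inf, n_na))
        mrp = out.get_reaction("Mrp")
        mrp.lower_bound = 0.0
        mrp.upper_bound = 0.0
    elif variant_id == "no_mrp":
        out.remove_reaction("Mrp")
    elif variant_id == "no_nrf":
        out.remove_reaction("Nrf")

    out.check_structure()
    return out


def add_pseudo_rnf(model: StoichiometricModel) -> StoichiometricModel:
    """Return a copy with the pseudo-Rnf added alongside HdrABC (both routes)."""
    out = model.copy()
    inf = out.parameters.get("bound_inf", 1000.0)
    n_na = out.parameters.get("rnf_na_out", 4)
    out.reactions.append(_pseudo_rnf(inf, n_na))
    out.check_structure()
    return out
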
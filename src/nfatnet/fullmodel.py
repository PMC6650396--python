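"""The full TCR-calcineurin-NFAT signalling network.

Topology covers the pathways downstream of MHC-triggered TCR activation:
the CN-NFAT axis (Ca2+-activated calcineurin dephosphorylates cytoplasmic
NFAT, translocating it to the nucleus), the Ras/MEK/ERK cascade, the
PI3K/Akt/GSK3 branch (with IL-2/IL-2R feeding back into PI3K), and the
NFAT-driven transcriptional programme (IL-2, FasL, TNFa, CTLA-4, RCAN,
Carabin). Eleven annotated feedback links shape the response:

positive toward nuclear NFAT
    NFAT/NFAT (transcriptional auto-induction), pRCAN/CN (phospho-RCAN
    binds calcineurin into a hyperactive complex), TNFa/TAK1 (TNFa
    activates TAK1, the RCAN kinase), PI3K/Akt, Akt/GSK3 (Akt inactivates
    GSK3b, the NFAT export kinase), PI3K/Rac1
negative
    RCAN/CN (unphosphorylated RCAN sequesters active CN), Carabin/CN,
    Carabin/Ras, CTLA4/TCR (induced CTLA-4 desensitizes TCR activation),
    CTLA4/PP2A (CTLA-4 activates the Akt phosphatase PP2A)

Kinetic-law assignment follows the type of each interaction: Hill kinetics
for transcription, Michaelis-Menten for enzyme catalysis, mass action for
binding/conversion. Reaction ids mirror the source numbering of the network
where one is documented (1, 2, 5, 7, 8, 9/26, 10, 19, 21, 43, 45, 52, 54,
59a, 61); auxiliary steps carry ids >= 100. A generic calcineurin inhibitor
(CnI) binds the active calcineurin conformation, the complex resolving to
the inactive pool with the inhibitor recycling.

``nominal_parameters()`` returns the package's calibrated default set: it
satisfies the qualitative calibration constraints (>= 2-fold NFAT and
>= 10-fold FasL secondary/primary induction, transient NFAT) and reproduces
the documented response classification under equal sequential pulses.
"""

from __future__ import annotations

from .network import (
    CANONICAL_LINKS,
    FeedbackLink,
    KineticLaw,
    LawForm,
    NetworkModel,
    Reaction,
    Species,
    SpeciesRole,
)
from .parameters import ParameterSet

S = SpeciesRole.SIGNALLING
T = SpeciesRole.TRANSCRIPT
C = SpeciesRole.COMPLEX

#: amplification-group display species of the sequential-stimulation analysis
REPORTED_SPECIES = (
    "pTCR", "CTLA4", "CaCN", "CN_RCAN", "CN_pRCAN", "RCAN", "pRCAN",
    "Carabin", "CN_Carabin", "NFATnuc", "IL2", "pIL2R", "FasL", "TNFa",
    "aRas", "aRas_Carabin", "pERK", "aPI3K", "pAkt", "aPP2A",
)


class _Builder:
    def __init__(self) -> None:
        self.reactions: list[Reaction] = []
        self.defaults: dict[str, float] = {}

    def _reg(self, rxn: Reaction, **values: float) -> None:
        self.reactions.append(rxn)
        self.defaults.update(values)

    def ma(self, rid, subs, prods, k, *, value, activators=(), inhibitors=(), inp=False):
        self._reg(
            Reaction(
                rid,
                KineticLaw(LawForm.MASS_ACTION, {"k": k}),
                substrates=tuple(subs),
                products=tuple(prods),
                activators=tuple(activators),
                inhibitors=tuple(inhibitors),
                driven_by_input=inp,
            ),
            **{k: value},
        )

    def mm(self, rid, sub, prod, *, Km, Km_value, kc=None, kc_value=None,
           Vmax=None, Vmax_value=None, enzyme=None, activators=(), act_values=(),
           enhancers=(), enh_values=(), inhibitors=(), inh_values=(), inp=False):
        params = {"Km": Km}
        vals = {Km: Km_value}
        if kc is not None:
            params["kc"] = kc
            vals[kc] = kc_value
        if Vmax is not None:
            params["Vmax"] = Vmax
            vals[Vmax] = Vmax_value
        for (sp, name), v in zip(activators, act_values):
            vals[name] = v
        for (sp, name), v in zip(enhancers, enh_values):
            vals[name] = v
        for (sp, name), v in zip(inhibitors, inh_values):
            vals[name] = v
        self._reg(
            Reaction(
                rid,
                KineticLaw(LawForm.MICHAELIS_MENTEN, params),
                substrates=((sub, 1),),
                products=((prod, 1),),
                enzyme=enzyme,
                activators=tuple(activators),
                enhancers=tuple(enhancers),
                inhibitors=tuple(inhibitors),
                driven_by_input=inp,
            ),
            **vals,
        )

    def hill(self, rid, regulator, product, *, Vmax, Vmax_value, Km, Km_value,
             n=2.0, basal=None, basal_value=None):
        params = {"Vmax": Vmax, "Km": Km}
        vals = {Vmax: Vmax_value, Km: Km_value}
        if basal is not None:
            params["basal"] = basal
            vals[basal] = basal_value
        self._reg(
            Reaction(
                rid,
                KineticLaw(LawForm.HILL, params, hill_n=n),
                products=((product, 1),),
                regulator=regulator,
            ),
            **vals,
        )


def _build() -> tuple[NetworkModel, dict[str, float]]:
    b = _Builder()

    # ---- TCR module (reaction 1 + desensitization/recycling) ----------
    b.mm("1", "TCR", "pTCR", Vmax="V_1", Vmax_value=3.0, Km="Km_1", Km_value=50.0,
         inhibitors=(("CTLA4", "kI_2c"),), inh_values=(0.3,), inp=True)
    b.ma("101", [("pTCR", 1)], [("TCR", 1)], "kd_1", value=0.1)
    b.ma("102", [("pTCR", 1)], [("iTCR", 1)], "kc_1i", value=0.15)  # internalization
    b.ma("103", [("iTCR", 1)], [("TCR", 1)], "kd_1r", value=0.0015)  # slow recycling

    # ---- calcineurin activation (reaction 5) and CnI binding ----------
    b.mm("5", "CN", "CaCN", Vmax="V_5", Vmax_value=60.0, Km="Km_5", Km_value=300.0,
         activators=(("pTCR", "Ka_5"),), act_values=(2e-4,))
    # CnI binds the catalytic domain of the active conformation; the complex
    # resolves to inactive CN with the inhibitor recycling.
    b.ma("104", [("CaCN", 1)], [("CN", 1)], "kd_5", value=0.25)
    b.ma("56", [("CaCN", 1), ("CnI", 1)], [("CN_CnI", 1)], "ka_56", value=0.001)
    b.ma("105", [("CN_CnI", 1)], [("CN", 1), ("CnI", 1)], "kd_56", value=1.0)

    # ---- RCAN feedbacks (reactions 7, 8, 19, 21) ----------------------
    # unphosphorylated RCAN binds (inactive) calcineurin, withholding it
    # from Ca2+ activation
    b.ma("7", [("RCAN", 1), ("CN", 1)], [("CN_RCAN", 1)], "ka_7", value=1e-4)
    b.ma("106", [("CN_RCAN", 1)], [("RCAN", 1), ("CN", 1)], "kd_7", value=60.0)
    b.mm("8", "RCAN", "pRCAN", Vmax="V_8", Vmax_value=2.0, Km="Km_8", Km_value=50.0,
         activators=(("aTAK1", "Ka_8"),), act_values=(2.0,))
    b.ma("107", [("pRCAN", 1)], [("RCAN", 1)], "kd_8", value=0.01)
    b.ma("19", [("pRCAN", 1), ("CaCN", 1)], [("CN_pRCAN", 1)], "ka_19", value=0.012)
    b.ma("108", [("CN_pRCAN", 1)], [("pRCAN", 1), ("CaCN", 1)], "kd_19", value=0.05)
    b.hill("21", "NFATnuc", "RCAN", Vmax="V_21", Vmax_value=0.5, Km="Km_21",
           Km_value=20.0, basal="basal_21", basal_value=0.001)
    b.ma("109", [("RCAN", 1)], [], "kdeg_21", value=5e-4)
    b.ma("110", [("pRCAN", 1)], [], "kdeg_23", value=5e-4)

    # ---- NFAT translocation cycle (reaction 10) -----------------------
    b.mm("10", "NFATcyt", "NFATnuc", kc="kc_10", kc_value=0.03, Km="Km_10",
         Km_value=400.0, enzyme="CaCN")
    b.mm("20", "NFATcyt", "NFATnuc", kc="kc_20", kc_value=0.15, Km="Km_20",
         Km_value=400.0, enzyme="CN_pRCAN")
    b.mm("11", "NFATnuc", "NFATcyt", kc="kc_11", kc_value=0.008, Km="Km_11",
         Km_value=100.0, enzyme="GSK3b")

    # ---- NFAT auto-induction and turnover -----------------------------
    b.hill("30", "NFATnuc", "NFATcyt", Vmax="V_30", Vmax_value=3.0, Km="Km_30",
           Km_value=20.0)
    b.ma("31", [], [("NFATcyt", 1)], "basal_31", value=0.02)
    b.ma("111", [("NFATcyt", 1)], [], "kdeg_32", value=2e-4)
    b.ma("112", [("NFATnuc", 1)], [], "kdeg_32b", value=2e-4)

    # ---- Carabin feedbacks (reactions 9/26 and 54) --------------------
    # Carabin returns active calcineurin to the inactive pool catalytically
    # (saturating in CaCN), giving the negative feedback a near-zero-order,
    # threshold-like character; a weak reversible CN/Carabin complex exists
    # alongside the catalytic cycle.
    b.hill("26", "NFATnuc", "Carabin", Vmax="V_26", Vmax_value=2.5, Km="Km_26",
           Km_value=85.0, n=4.0, basal="basal_26", basal_value=0.001)
    b.ma("113", [("Carabin", 1)], [], "kdeg_26", value=3e-4)
    b.mm("9", "CaCN", "CN", kc="kc_9", kc_value=1.4, Km="Km_9", Km_value=20.0,
         enzyme="Carabin")
    b.ma("9b", [("Carabin", 1), ("CaCN", 1)], [("CN_Carabin", 1)], "ka_9", value=1e-4)
    b.ma("114", [("CN_Carabin", 1)], [("Carabin", 1), ("CaCN", 1)], "kd_9", value=0.1)
    b.ma("54", [("Carabin", 1), ("aRas", 1)], [("aRas_Carabin", 1)], "ka_54", value=0.001)
    b.ma("115", [("aRas_Carabin", 1)], [("Carabin", 1), ("aRas", 1)], "kd_54", value=0.05)

    # ---- CTLA-4 feedback (reactions 2, 61) ----------------------------
    b.hill("2", "NFATnuc", "CTLA4", Vmax="V_2", Vmax_value=0.03, Km="Km_2",
           Km_value=15.0)
    b.ma("116", [("CTLA4", 1)], [], "kdeg_2", value=1.5e-4)
    b.mm("40", "PP2A", "aPP2A", kc="kc_40", kc_value=0.04, Km="Km_40",
         Km_value=100.0, enzyme="CTLA4")
    b.ma("117", [("PP2A", 1)], [("aPP2A", 1)], "kc_40b", value=0.005)
    b.ma("118", [("aPP2A", 1)], [("PP2A", 1)], "kd_40", value=0.05)
    b.mm("61", "pAkt", "Akt", kc="kc_61", kc_value=0.02, Km="Km_61",
         Km_value=100.0, enzyme="aPP2A")

    # ---- TNFa / TAK1 feedback -----------------------------------------
    b.hill("34", "NFATnuc", "TNFa", Vmax="V_34", Vmax_value=0.05, Km="Km_34",
           Km_value=10.0, basal="basal_34", basal_value=0.002)
    b.ma("119", [("TNFa", 1)], [], "kdeg_34", value=2e-4)
    b.mm("35", "TAK1", "aTAK1", Vmax="V_35", Vmax_value=1.0, Km="Km_35",
         Km_value=100.0, activators=(("TNFa", "Ka_35"),), act_values=(20.0,))
    b.ma("120", [("aTAK1", 1)], [("TAK1", 1)], "kd_35", value=0.1)

    # ---- IL-2 axis (reactions 43, 45) ---------------------------------
    b.hill("43", "NFATnuc", "IL2mRNA", Vmax="V_43", Vmax_value=0.2, Km="Km_43",
           Km_value=120.0)
    b.ma("121", [("IL2mRNA", 1)], [], "kdeg_43", value=2e-3)
    b.ma("44", [("IL2mRNA", 1)], [("IL2mRNA", 1), ("IL2", 1)], "kc_44", value=0.02)
    b.ma("122", [("IL2", 1)], [], "kdeg_44", value=1e-3)
    b.mm("45", "IL2R", "pIL2R", Vmax="V_45", Vmax_value=2.0, Km="Km_45",
         Km_value=100.0, activators=(("IL2", "Ka_45"),), act_values=(50.0,))
    b.ma("123", [("pIL2R", 1)], [("IL2R", 1)], "kd_45", value=0.05)

    # ---- FasL output ---------------------------------------------------
    b.hill("47", "NFATnuc", "FasL", Vmax="V_47", Vmax_value=0.3, Km="Km_47",
           Km_value=175.0, n=4.0, basal="basal_47", basal_value=1e-4)
    b.ma("124", [("FasL", 1)], [], "kdeg_47", value=1e-3)

    # ---- Ras / MEK / ERK (reaction 52) --------------------------------
    b.mm("52", "Ras", "aRas", Vmax="V_52", Vmax_value=10.0, Km="Km_52",
         Km_value=100.0, activators=(("pTCR", "Ka_52"),), act_values=(2.0,))
    b.ma("125", [("aRas", 1)], [("Ras", 1)], "kd_52", value=0.1)
    b.mm("55", "MEK", "pMEK", kc="kc_55", kc_value=0.3, Km="Km_55",
         Km_value=200.0, enzyme="aRas")
    b.ma("126", [("pMEK", 1)], [("MEK", 1)], "kd_55", value=0.3)
    b.mm("57", "ERK", "pERK", kc="kc_57", kc_value=0.3, Km="Km_57",
         Km_value=200.0, enzyme="pMEK")
    b.ma("127", [("pERK", 1)], [("ERK", 1)], "kd_57", value=0.3)

    # ---- PI3K / Akt / GSK3 / Rac1 (reactions 59a, 61 partner steps) ---
    b.mm("59a", "PI3K", "aPI3K", Vmax="V_59a", Vmax_value=8.0, Km="Km_59a",
         Km_value=100.0, activators=(("pTCR", "Ka_59a"),), act_values=(10.0,))
    b.mm("46", "PI3K", "aPI3K", Vmax="V_46", Vmax_value=0.2, Km="Km_46",
         Km_value=100.0, activators=(("pIL2R", "Ka_46"),), act_values=(100.0,))
    b.mm("63", "PI3K", "aPI3K", Vmax="V_63", Vmax_value=0.5, Km="Km_63",
         Km_value=100.0, activators=(("aRac1", "Ka_63"),), act_values=(50.0,))
    b.ma("128", [("aPI3K", 1)], [("PI3K", 1)], "kd_59", value=0.15)
    b.mm("59b", "Akt", "pAkt", kc="kc_59b", kc_value=0.02, Km="Km_59b",
         Km_value=100.0, enzyme="aPI3K")
    b.mm("60", "GSK3b", "pGSK3b", kc="kc_60", kc_value=0.005, Km="Km_60",
         Km_value=100.0, enzyme="pAkt")
    b.ma("129", [("pGSK3b", 1)], [("GSK3b", 1)], "kd_60", value=0.05)
    b.mm("62", "Rac1", "aRac1", kc="kc_62", kc_value=0.002, Km="Km_62",
         Km_value=100.0, enzyme="aPI3K")
    b.ma("130", [("aRac1", 1)], [("Rac1", 1)], "kd_62", value=0.05)

    species = (
        Species("TCR", S, 100.0), Species("pTCR", S), Species("iTCR", S),
        Species("CTLA4", T),
        Species("CN", S, 1000.0), Species("CaCN", S),
        Species("CN_RCAN", C), Species("CN_pRCAN", C), Species("CN_Carabin", C),
        Species("CnI", SpeciesRole.INPUT), Species("CN_CnI", C),
        Species("RCAN", T), Species("pRCAN", S),
        Species("Carabin", T),
        Species("NFATcyt", S), Species("NFATnuc", S),
        Species("IL2mRNA", T), Species("IL2", T),
        Species("IL2R", S, 100.0), Species("pIL2R", S),
        Species("FasL", T), Species("TNFa", T),
        Species("TAK1", S, 100.0), Species("aTAK1", S),
        Species("Ras", S, 100.0), Species("aRas", S), Species("aRas_Carabin", C),
        Species("MEK", S, 200.0), Species("pMEK", S),
        Species("ERK", S, 200.0), Species("pERK", S),
        Species("PI3K", S, 100.0), Species("aPI3K", S),
        Species("Akt", S, 100.0), Species("pAkt", S),
        Species("PP2A", S, 100.0), Species("aPP2A", S),
        Species("GSK3b", S, 100.0), Species("pGSK3b", S),
        Species("Rac1", S, 100.0), Species("aRac1", S),
    )

    links = {
        "NFAT/NFAT": {"V_30"},
        "pRCAN/CN": {"ka_19"},
        "RCAN/CN": {"ka_7"},
        "Carabin/CN": {"ka_9"},
        "Carabin/Ras": {"ka_54"},
        "CTLA4/TCR": {"kI_2c"},
        "CTLA4/PP2A": {"kc_40"},
        "TNFa/TAK1": {"V_35"},
        "PI3K/Akt": {"kc_59b"},
        "Akt/GSK3": {"kc_60"},
        "PI3K/Rac1": {"kc_62"},
    }
    feedback = tuple(
        FeedbackLink(name, CANONICAL_LINKS[name], frozenset(params))
        for name, params in links.items()
    )

    moieties = {
        "CN_total": ("CN", "CaCN", "CN_RCAN", "CN_pRCAN", "CN_Carabin", "CN_CnI"),
        "TCR_total": ("TCR", "pTCR", "iTCR"),
        "NFAT_total": ("NFATcyt", "NFATnuc"),
        "RCAN_total": ("RCAN", "pRCAN", "CN_RCAN", "CN_pRCAN"),
        "Carabin_total": ("Carabin", "CN_Carabin", "aRas_Carabin"),
        "Ras_total": ("Ras", "aRas", "aRas_Carabin"),
        "IL2R_total": ("IL2R", "pIL2R"),
        "TAK1_total": ("TAK1", "aTAK1"),
        "MEK_total": ("MEK", "pMEK"),
        "ERK_total": ("ERK", "pERK"),
        "PI3K_total": ("PI3K", "aPI3K"),
        "Akt_total": ("Akt", "pAkt"),
        "PP2A_total": ("PP2A", "aPP2A"),
        "GSK3_total": ("GSK3b", "pGSK3b"),
        "Rac1_total": ("Rac1", "aRac1"),
        "CnI_total": ("CnI", "CN_CnI"),
    }

    model = NetworkModel(
        name="tcr-cn-nfat-full",
        species=species,
        reactions=tuple(b.reactions),
        feedback_links=feedback,
        inputs=("MHC", "CnI"),
        conserved_moieties=moieties,
    )
    return model, b.defaults


_MODEL, _DEFAULTS = _build()

#: reactions implementing synthesis or decay; disabling them closes the
#: NFAT / RCAN / Carabin moieties (used by the conservation tests)
SYNTHESIS_DECAY_RIDS = (
    "21", "109", "110", "30", "31", "111", "112", "26", "113", "2", "116",
    "34", "119", "43", "121", "44", "122", "47", "124",
)


def build_full_network() -> NetworkModel:
    """The full network; structure only (values live in ``nominal_parameters``)."""
    model, _ = _build()
    return model


def nominal_parameters() -> ParameterSet:
    """Calibrated nominal kinetic constants for the full network."""
    return ParameterSet(dict(_DEFAULTS), provenance="fitted")
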
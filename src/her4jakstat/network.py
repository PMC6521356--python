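"""Reaction-network representation of the HER4–JAK2–STAT5 pathway.

The model is a two-compartment (cytoplasm/nucleus) deterministic reaction
network.  The canonical core follows the literature JAK-STAT wiring: the
HER4 receptor pre-associates with the JAK2 kinase, the ligand neuregulin
(NRG) binds and activates the complex, activated receptor phosphorylates
cytoplasmic STAT5, phosphorylated STAT5 dimerizes and is imported into the
nucleus where it drives Hill-type transcription of SOCS and beta-casein.
SOCS protein feeds back negatively on the activated receptor complex; a
nuclear phosphatase (PPN) recycles the STAT5 dimer, and cytoplasmic
phosphatases (SHP, PPX) deactivate the receptor and STAT5 monomer.

Two optional extensions can be switched on:

* competitive heterodimerization — ligand-bound HER4 pairs with a lumped
  HER2/HER3 partner pool, draining free HER4 away from the JAK channel
  (three reactions, ids R41/R42/R43);
* a JAK-independent branch — proteolytic release of the HER4 s80/4ICD
  fragment which, once active, phosphorylates STAT5 directly at a lower
  rate and is immune to SOCS feedback (three reactions, R36/R37/R39).

Units: concentrations in nM, time in hours.  Second-order rate constants
are nM^-1 h^-1, first-order h^-1, the Hill Vmax nM h^-1 and the Hill
half-saturation constant nM.  Compartment volumes are relative (cytoplasm
1.0); transport fluxes are scaled by the volume ratio so that molecule
*amounts*, not concentrations, are conserved across compartments.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "Compartment",
    "Species",
    "RateLaw",
    "Reaction",
    "ReactionNetwork",
    "build_canonical_network",
    "build_full_network",
    "add_heterodimerization",
    "add_jak_independent_branch",
    "reaction_rate",
    "ode_rhs",
    "stoichiometry_matrix",
    "effective_stoichiometry_matrix",
    "boundary_mask",
    "conservation_vectors",
    "stat5_moiety_vector",
    "load_baseline_parameters",
    "network_to_config",
    "network_from_config",
]

MASS_ACTION_IRREVERSIBLE = "mass_action_irreversible"
MASS_ACTION_REVERSIBLE = "mass_action_reversible"
HILL_ACTIVATION = "hill_activation"
FIRST_ORDER_TRANSPORT = "first_order_transport"

_RATE_LAW_KINDS = {
    MASS_ACTION_IRREVERSIBLE,
    MASS_ACTION_REVERSIBLE,
    HILL_ACTIVATION,
    FIRST_ORDER_TRANSPORT,
}

SPECIES_ROLES = {
    "ligand",
    "receptor",
    "kinase",
    "phosphatase",
    "transcription_factor",
    "mRNA",
    "protein",
    "complex",
}


@dataclass
class Compartment:
    id: str
    name: str
    volume: float

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"compartment {self.id!r}: volume must be > 0")


@dataclass
class Species:
    """A model species.

    ``boundary=True`` marks a species with clamped concentration (its ODE
    derivative is zero even though reactions consume it) — used for the
    ligand NRG, which sits in the extracellular medium in effective excess.
    """

    id: str
    name: str
    compartment: str
    initial_amount: float = 0.0
    role: str = "protein"
    boundary: bool = False

    def __post_init__(self) -> None:
        if self.initial_amount < 0:
            raise ValueError(f"species {self.id!r}: initial_amount must be >= 0")
        if self.role not in SPECIES_ROLES:
            raise ValueError(f"species {self.id!r}: unknown role {self.role!r}")


@dataclass
class RateLaw:
    """Kinetic law attached to a reaction.

    ``params`` maps rate-law roles (``kf``, ``kr``, ``V_transc``,
    ``K_transc``, ``n_transc``, ``k_transport``) to parameter ids in the
    network-wide parameter table.
    """

    kind: str
    params: dict[str, str]

    def __post_init__(self) -> None:
        if self.kind not in _RATE_LAW_KINDS:
            raise ValueError(f"unknown rate-law kind {self.kind!r}")
        required = {
            MASS_ACTION_IRREVERSIBLE: {"kf"},
            MASS_ACTION_REVERSIBLE: {"kf", "kr"},
            HILL_ACTIVATION: {"V_transc", "K_transc", "n_transc"},
            FIRST_ORDER_TRANSPORT: {"k_transport"},
        }[self.kind]
        missing = required - set(self.params)
        if missing:
            raise ValueError(f"rate law {self.kind}: missing roles {sorted(missing)}")


@dataclass
class Reaction:
    id: str
    name: str
    reactants: list[tuple[str, int]]
    products: list[tuple[str, int]]
    rate_law: RateLaw
    modifiers: list[str] = field(default_factory=list)


class ReactionNetwork:
    """In-memory pathway model: compartments, species, reactions, parameters."""

    def __init__(
        self,
        compartments: list[Compartment],
        species: list[Species],
        reactions: list[Reaction],
        parameters: dict[str, float],
        heterodimerization_on: bool = False,
        jak_independent_on: bool = False,
    ) -> None:
        self.compartments = list(compartments)
        self.species = list(species)
        self.reactions = list(reactions)
        self.parameters = dict(parameters)
        self.heterodimerization_on = heterodimerization_on
        self.jak_independent_on = jak_independent_on
        self.validate()

    # -- bookkeeping ----------------------------------------------------
    def validate(self) -> None:
        comp_ids = [c.id for c in self.compartments]
        sp_ids = [s.id for s in self.species]
        rxn_ids = [r.id for r in self.reactions]
        for ids, what in ((comp_ids, "compartment"), (sp_ids, "species"), (rxn_ids, "reaction")):
            if len(ids) != len(set(ids)):
                dup = sorted({i for i in ids if ids.count(i) > 1})
                raise ValueError(f"duplicate {what} ids: {dup}")
        comp_set = set(comp_ids)
        sp_set = set(sp_ids)
        for s in self.species:
            if s.compartment not in comp_set:
                raise ValueError(f"species {s.id!r}: unknown compartment {s.compartment!r}")
        for r in self.reactions:
            for sid, stoich in r.reactants + r.products:
                if sid not in sp_set:
                    raise ValueError(f"reaction {r.id!r}: unknown species {sid!r}")
                if stoich < 1 or int(stoich) != stoich:
                    raise ValueError(f"reaction {r.id!r}: stoichiometry must be a positive integer")
            for sid in r.modifiers:
                if sid not in sp_set:
                    raise ValueError(f"reaction {r.id!r}: unknown modifier {sid!r}")
            for role, pid in r.rate_law.params.items():
                if pid not in self.parameters:
                    raise ValueError(f"reaction {r.id!r}: parameter {pid!r} ({role}) not in table")
            if r.rate_law.kind == FIRST_ORDER_TRANSPORT:
                if len(r.reactants) != 1 or len(r.products) != 1:
                    raise ValueError(f"transport {r.id!r} must have one reactant and one product")
                src = self.species_by_id(r.reactants[0][0]).compartment
                dst = self.species_by_id(r.products[0][0]).compartment
                if src == dst:
                    raise ValueError(f"transport {r.id!r} must cross compartments")
            if r.rate_law.kind == HILL_ACTIVATION and len(r.modifiers) != 1:
                raise ValueError(f"hill reaction {r.id!r} needs exactly one modifier")
        if "K_transc" in self.parameters and self.parameters["K_transc"] <= 0:
            raise ValueError("K_transc must be > 0")
        if "n_transc" in self.parameters and self.parameters["n_transc"] < 1:
            raise ValueError("n_transc must be >= 1")

    def copy(self) -> "ReactionNetwork":
        return copy.deepcopy(self)

    def species_by_id(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def reaction_by_id(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def compartment_by_id(self, cid: str) -> Compartment:
        for c in self.compartments:
            if c.id == cid:
                return c
        raise KeyError(cid)

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def species_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_amount for s in self.species], dtype=float)

    def species_volumes(self) -> np.ndarray:
        vol = {c.id: c.volume for c in self.compartments}
        return np.array([vol[s.compartment] for s in self.species], dtype=float)

    def reaction_compartment(self, rxn: Reaction) -> str:
        """Compartment in which the rate law is evaluated (reactant side)."""
        if rxn.reactants:
            return self.species_by_id(rxn.reactants[0][0]).compartment
        if rxn.modifiers:
            return self.species_by_id(rxn.modifiers[0]).compartment
        if rxn.products:
            return self.species_by_id(rxn.products[0][0]).compartment
        raise ValueError(f"reaction {rxn.id!r} has no participants")


# ---------------------------------------------------------------------------
# Baseline parameters
# ---------------------------------------------------------------------------

def load_baseline_parameters() -> dict:
    """Load the packaged baseline parameter/initial-amount file."""
    ref = importlib.resources.files("her4jakstat.data") / "parameters.yaml"
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def _ma(kf: str, kr: str | None = None) -> RateLaw:
    if kr is None:
        return RateLaw(MASS_ACTION_IRREVERSIBLE, {"kf": kf})
    return RateLaw(MASS_ACTION_REVERSIBLE, {"kf": kf, "kr": kr})


def _transport(k: str) -> RateLaw:
    return RateLaw(FIRST_ORDER_TRANSPORT, {"k_transport": k})


_HILL = RateLaw(
    HILL_ACTIVATION,
    {"V_transc": "V_transc", "K_transc": "K_transc", "n_transc": "n_transc"},
)


def build_canonical_network(parameters: dict | None = None) -> ReactionNetwork:
    """Construct the canonical (literature) JAK-dependent pathway.

    Both extension flags start out off; see :func:`add_heterodimerization`
    and :func:`add_jak_independent_branch`.
    """
    data = parameters if parameters is not None else load_baseline_parameters()
    params = dict(data["parameters"])
    init = dict(data["initial_amounts"])
    vols = data.get("compartments", {"cyt": 1.0, "nuc": 0.25})

    compartments = [
        Compartment("cyt", "cytoplasm", float(vols["cyt"])),
        Compartment("nuc", "nucleus", float(vols["nuc"])),
    ]

    def sp(sid, name, comp, role, boundary=False):
        return Species(sid, name, comp, float(init.get(sid, 0.0)), role, boundary)

    species = [
        sp("NRG", "neuregulin", "cyt", "ligand", boundary=True),
        sp("HER4", "HER4 receptor", "cyt", "receptor"),
        sp("JAK", "JAK2 kinase", "cyt", "kinase"),
        sp("HER4_JAK", "HER4:JAK2 complex", "cyt", "complex"),
        sp("NRG_HER4_JAK", "NRG:HER4:JAK2 complex", "cyt", "complex"),
        sp("HER4_JAK_act", "activated HER4:JAK2 complex", "cyt", "complex"),
        sp("SHP", "SHP phosphatase", "cyt", "phosphatase"),
        sp("PPX", "PPX phosphatase", "cyt", "phosphatase"),
        sp("STATc", "cytoplasmic STAT5", "cyt", "transcription_factor"),
        sp("STATc_p", "phospho-STAT5", "cyt", "transcription_factor"),
        sp("STATdim_c", "cytoplasmic STAT5 dimer", "cyt", "transcription_factor"),
        sp("STATdim_n", "nuclear STAT5 dimer", "nuc", "transcription_factor"),
        sp("PPN", "nuclear phosphatase PPN", "nuc", "phosphatase"),
        sp("STATdim_n_PPN", "nuclear STAT5 dimer:PPN", "nuc", "complex"),
        sp("STATn", "nuclear STAT5 monomer", "nuc", "transcription_factor"),
        sp("mRNA_SOCS_n", "nuclear SOCS mRNA", "nuc", "mRNA"),
        sp("mRNA_SOCS_c", "cytoplasmic SOCS mRNA", "cyt", "mRNA"),
        sp("SOCS", "SOCS protein", "cyt", "protein"),
        sp("SOCS_HER4_JAK", "SOCS:HER4:JAK2 complex", "cyt", "complex"),
        sp("SOCS_HER4_JAK_SHP", "SOCS:HER4:JAK2:SHP complex", "cyt", "complex"),
        sp("mRNA_cas_n", "nuclear beta-casein mRNA", "nuc", "mRNA"),
        sp("mRNA_cas_c", "cytoplasmic beta-casein mRNA", "cyt", "mRNA"),
        sp("casein", "beta-casein protein", "cyt", "protein"),
    ]

    reactions = [
        Reaction("R01", "HER4 JAK Binding",
                 [("HER4", 1), ("JAK", 1)], [("HER4_JAK", 1)], _ma("kfR01", "krR01")),
        Reaction("R02", "NRG HER4 JAK Binding",
                 [("NRG", 1), ("HER4_JAK", 1)], [("NRG_HER4_JAK", 1)], _ma("kfR02")),
        Reaction("R03", "HER4 JAK Activation",
                 [("NRG_HER4_JAK", 1)], [("HER4_JAK_act", 1)], _ma("kR03")),
        Reaction("R05", "Receptor Dephosphorylation SHP",
                 [("HER4_JAK_act", 1), ("SHP", 1)], [("HER4_JAK", 1), ("SHP", 1)],
                 _ma("kR05")),
        Reaction("R06", "STATc Phosphorylation JAK Dependent",
                 [("HER4_JAK_act", 1), ("STATc", 1)],
                 [("HER4_JAK_act", 1), ("STATc_p", 1)], _ma("kR06")),
        Reaction("R08", "STATc Dephosphorylation PPX",
                 [("STATc_p", 1), ("PPX", 1)], [("STATc", 1), ("PPX", 1)], _ma("kR08")),
        Reaction("R12", "STAT Dimerization",
                 [("STATc_p", 2)], [("STATdim_c", 1)], _ma("kR12")),
        Reaction("R15", "STAT Dimer Nuclear Translocation",
                 [("STATdim_c", 1)], [("STATdim_n", 1)], _transport("kR15")),
        Reaction("R19", "Nuclear STAT Dimer PPN Binding",
                 [("STATdim_n", 1), ("PPN", 1)], [("STATdim_n_PPN", 1)], _ma("kfR19")),
        Reaction("R20", "Nuclear STAT dimer dephosphorylation",
                 [("STATdim_n_PPN", 1)], [("STATn", 2), ("PPN", 1)], _ma("kR20")),
        Reaction("R21", "STAT Nuclear Export",
                 [("STATn", 1)], [("STATc", 1)], _transport("kR21")),
        Reaction("R22", "SOCS Transcription",
                 [], [("mRNA_SOCS_n", 1)], _HILL, modifiers=["STATdim_n"]),
        Reaction("R24", "mRNA Nuclear Export",
                 [("mRNA_SOCS_n", 1)], [("mRNA_SOCS_c", 1)], _transport("kR24")),
        Reaction("R25", "Translation",
                 [("mRNA_SOCS_c", 1)], [("mRNA_SOCS_c", 1), ("SOCS", 1)], _ma("kR25")),
        Reaction("R26", "SOCS mRNA Degradation",
                 [("mRNA_SOCS_c", 1)], [], _ma("kR26")),
        Reaction("R27", "SOCS Degradation",
                 [("SOCS", 1)], [], _ma("kR27")),
        Reaction("R28", "SOCS Mediated negative feedback",
                 [("SOCS", 1), ("HER4_JAK_act", 1)], [("SOCS_HER4_JAK", 1)],
                 _ma("SOCS_Binding_Rate")),
        Reaction("R29", "STATc SOCS HER4 JAK SHP Binding",
                 [("SOCS_HER4_JAK", 1), ("SHP", 1)], [("SOCS_HER4_JAK_SHP", 1)],
                 _ma("kfR29")),
        Reaction("R30", "SOCS Complex Dissociation",
                 [("SOCS_HER4_JAK_SHP", 1)],
                 [("HER4", 1), ("JAK", 1), ("SOCS", 1), ("SHP", 1)], _ma("kR30")),
        Reaction("R44", "Casein Transcription",
                 [], [("mRNA_cas_n", 1)], _HILL, modifiers=["STATdim_n"]),
        Reaction("R45", "mRNA Nuclear Export Casein",
                 [("mRNA_cas_n", 1)], [("mRNA_cas_c", 1)], _transport("kR45")),
        Reaction("R46", "mRNA degradation rate",
                 [("mRNA_cas_c", 1)], [], _ma("kR46")),
        Reaction("R47", "Casein Translation",
                 [("mRNA_cas_c", 1)], [("mRNA_cas_c", 1), ("casein", 1)], _ma("kR47")),
        # HC/GR-driven basal transcription: the experiments' hydrocortisone
        # control expresses beta-casein without NRG; readouts normalize to it.
        Reaction("R48", "Basal Casein Transcription",
                 [], [("mRNA_cas_n", 1)], _ma("k_basal_cas")),
    ]

    used = {pid for r in reactions for pid in r.rate_law.params.values()}
    core_params = {pid: float(params[pid]) for pid in sorted(used)}
    # ship extension constants too so toggling branches never changes the table
    for pid in ("kfR41", "krR41", "kfR42", "krR42", "kfR43", "krR43",
                "kfR36", "kR37", "kR39"):
        core_params[pid] = float(params[pid])

    return ReactionNetwork(compartments, species, reactions, core_params)


def add_heterodimerization(net: ReactionNetwork) -> ReactionNetwork:
    """Add the three competitive HER4 heterodimerization reactions.

    A lumped partner-receptor pool (HER2+HER3, species ``ERBB``) captures
    free HER4 either ligand-dependently or constitutively, competing with
    HER4–JAK binding for the same HER4 pool.
    """
    if net.heterodimerization_on:
        raise ValueError("heterodimerization reactions already present")
    net = net.copy()
    init = load_baseline_parameters()["initial_amounts"]
    net.species += [
        Species("ERBB", "HER2/HER3 partner pool", "cyt", float(init.get("ERBB", 0.0)), "receptor"),
        Species("HET", "HER4:partner heterodimer", "cyt", 0.0, "complex"),
        Species("HET_L", "ligand-bound HER4:partner heterodimer", "cyt", 0.0, "complex"),
    ]
    net.reactions += [
        # reversible: the fast, favorable heterodimer pool equilibrates with
        # free HER4, buffering it at a fraction that shrinks with NRG dose
        Reaction("R41", "HER4 Heterodimerization",
                 [("NRG", 1), ("HER4", 1), ("ERBB", 1)], [("HET_L", 1)],
                 _ma("kfR41", "krR41")),
        Reaction("R42", "HER4 Heterodimerization Constitutive",
                 [("HER4", 1), ("ERBB", 1)], [("HET", 1)], _ma("kfR42", "krR42")),
        Reaction("R43", "HER4 Heterodimer Ligand Binding",
                 [("NRG", 1), ("HET", 1)], [("HET_L", 1)], _ma("kfR43", "krR43")),
    ]
    net.heterodimerization_on = True
    net.validate()
    return net


def add_jak_independent_branch(net: ReactionNetwork) -> ReactionNetwork:
    """Add the slower JAK-independent s80/4ICD branch (three reactions).

    Ligand-stimulated cleavage of HER4 releases the s80 fragment, which
    activates and then phosphorylates STAT5 directly.  The branch is not a
    substrate of the SOCS feedback reaction, and its phosphorylation rate
    (kR39) is an order of magnitude below the JAK-dependent one (kR06).
    """
    if net.jak_independent_on:
        raise ValueError("JAK-independent branch already present")
    net = net.copy()
    net.species += [
        Species("s80", "HER4 s80/4ICD fragment", "cyt", 0.0, "complex"),
        Species("s80_act", "activated s80 fragment", "cyt", 0.0, "complex"),
    ]
    net.reactions += [
        Reaction("R36", "IFNR (HER4 s80) Formation",
                 [("NRG", 1), ("HER4", 1)], [("s80", 1)], _ma("kfR36")),
        Reaction("R37", "IFNR (HER4 s80) Activation",
                 [("s80", 1)], [("s80_act", 1)], _ma("kR37")),
        Reaction("R39", "STATc Phosphorylation JAK independent",
                 [("s80_act", 1), ("STATc", 1)], [("s80_act", 1), ("STATc_p", 1)],
                 _ma("kR39")),
    ]
    net.jak_independent_on = True
    net.validate()
    return net


def build_full_network(parameters: dict | None = None) -> ReactionNetwork:
    """Canonical core plus both extensions (the combined model)."""
    return add_jak_independent_branch(
        add_heterodimerization(build_canonical_network(parameters))
    )


# ---------------------------------------------------------------------------
# Rates and ODE right-hand side
# ---------------------------------------------------------------------------

_NEG_TOL = 1e-9


def reaction_rate(
    rxn: Reaction,
    state: np.ndarray | dict[str, float],
    params: dict[str, float],
    species_index: dict[str, int] | None = None,
) -> float:
    """Evaluate a reaction's rate law (nM/h, in the reaction's compartment).

    ``state`` is either a concentration vector (with ``species_index``
    mapping ids to positions) or a mapping of species id -> concentration.
    """
    if isinstance(state, dict):
        conc = state.__getitem__
    else:
        if species_index is None:
            raise ValueError("species_index required with a vector state")
        conc = lambda sid: state[species_index[sid]]

    involved = [sid for sid, _ in rxn.reactants + rxn.products] + list(rxn.modifiers)
    for sid in involved:
        if conc(sid) < -_NEG_TOL:
            raise ValueError(f"negative concentration for {sid!r}: {conc(sid)}")

    law = rxn.rate_law
    p = {role: params[pid] for role, pid in law.params.items()}
    if law.kind == MASS_ACTION_IRREVERSIBLE:
        v = p["kf"]
        for sid, st in rxn.reactants:
            v *= max(conc(sid), 0.0) ** st
        return v
    if law.kind == MASS_ACTION_REVERSIBLE:
        vf = p["kf"]
        for sid, st in rxn.reactants:
            vf *= max(conc(sid), 0.0) ** st
        vr = p["kr"]
        for sid, st in rxn.products:
            vr *= max(conc(sid), 0.0) ** st
        return vf - vr
    if law.kind == HILL_ACTIVATION:
        m = max(conc(rxn.modifiers[0]), 0.0)
        V, K, n = p["V_transc"], p["K_transc"], p["n_transc"]
        if m == 0.0:
            return 0.0
        mn = m ** n
        return V * mn / (K ** n + mn)
    # first-order transport
    return p["k_transport"] * max(conc(rxn.reactants[0][0]), 0.0)


def stoichiometry_matrix(net: ReactionNetwork) -> np.ndarray:
    """Net stoichiometry matrix S (n_species x n_reactions), amount units."""
    idx = net.species_index
    S = np.zeros((len(net.species), len(net.reactions)))
    for j, r in enumerate(net.reactions):
        for sid, st in r.reactants:
            S[idx[sid], j] -= st
        for sid, st in r.products:
            S[idx[sid], j] += st
    return S


def boundary_mask(net: ReactionNetwork) -> np.ndarray:
    return np.array([s.boundary for s in net.species], dtype=bool)


def effective_stoichiometry_matrix(net: ReactionNetwork) -> np.ndarray:
    """Stoichiometry matrix with boundary-species rows zeroed (the matrix
    actually governing the ODEs)."""
    S = stoichiometry_matrix(net)
    S[boundary_mask(net), :] = 0.0
    return S


def conservation_vectors(net: ReactionNetwork, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the left null space of the effective
    stoichiometry matrix.

    Each row w satisfies w @ S = 0, i.e. sum_i w_i * amount_i is conserved
    along every trajectory.
    """
    S = effective_stoichiometry_matrix(net)
    u, s, _ = np.linalg.svd(S)
    rank = int(np.sum(s > tol * (s[0] if s.size else 1.0)))
    return u[:, rank:].T


def stat5_moiety_vector(net: ReactionNetwork) -> np.ndarray:
    """Weights of the total-STAT5 conservation moiety (amount units)."""
    weights = {
        "STATc": 1, "STATc_p": 1, "STATdim_c": 2,
        "STATdim_n": 2, "STATdim_n_PPN": 2, "STATn": 1,
    }
    w = np.zeros(len(net.species))
    for sid, wt in weights.items():
        w[net.species_index[sid]] = wt
    return w


def ode_rhs(net: ReactionNetwork, state: np.ndarray, t: float = 0.0,
            params: dict[str, float] | None = None) -> np.ndarray:
    """dC/dt = (1/V_i) * sum_r S_ir * v_r, with v_r in amount/h.

    Reference implementation used for validation; simulations go through
    the compiled form in :mod:`her4jakstat.simulate`.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (len(net.species),):
        raise ValueError("state length must equal the number of species")
    if not np.all(np.isfinite(state)):
        raise ValueError("state contains NaN/Inf")
    params = params if params is not None else net.parameters
    idx = net.species_index
    vol = {c.id: c.volume for c in net.compartments}
    v_subst = np.empty(len(net.reactions))
    for j, r in enumerate(net.reactions):
        v_subst[j] = reaction_rate(r, state, params, idx) * vol[net.reaction_compartment(r)]
    S = effective_stoichiometry_matrix(net)
    return (S @ v_subst) / net.species_volumes()


# ---------------------------------------------------------------------------
# Config (de)serialization
# ---------------------------------------------------------------------------

def network_to_config(net: ReactionNetwork) -> dict:
    """Human-editable structured representation of the network."""
    return {
        "compartments": [
            {"id": c.id, "name": c.name, "volume": c.volume} for c in net.compartments
        ],
        "species": [
            {"id": s.id, "name": s.name, "compartment": s.compartment,
             "initial_amount": s.initial_amount, "role": s.role,
             "boundary": s.boundary}
            for s in net.species
        ],
        "reactions": [
            {"id": r.id, "name": r.name,
             "reactants": [list(x) for x in r.reactants],
             "products": [list(x) for x in r.products],
             "modifiers": list(r.modifiers),
             "rate_law": {"kind": r.rate_law.kind, "params": dict(r.rate_law.params)}}
            for r in net.reactions
        ],
        "parameters": dict(net.parameters),
        "flags": {
            "heterodimerization_on": net.heterodimerization_on,
            "jak_independent_on": net.jak_independent_on,
        },
    }


def network_from_config(cfg: dict) -> ReactionNetwork:
    comps = [Compartment(**c) for c in cfg["compartments"]]
    species = [Species(**s) for s in cfg["species"]]
    reactions = [
        Reaction(
            r["id"], r["name"],
            [tuple(x) for x in r["reactants"]],
            [tuple(x) for x in r["products"]],
            RateLaw(r["rate_law"]["kind"], dict(r["rate_law"]["params"])),
            modifiers=list(r.get("modifiers", [])),
        )
        for r in cfg["reactions"]
    ]
    flags = cfg.get("flags", {})
    return ReactionNetwork(
        comps, species, reactions, dict(cfg["parameters"]),
        heterodimerization_on=bool(flags.get("heterodimerization_on", False)),
        jak_independent_on=bool(flags.get("jak_independent_on", False)),
    )
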
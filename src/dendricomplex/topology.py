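"""Residue-level dendrimer topology builder and structural bookkeeping.

A lysine dendrimer of generation *g* is modelled as one neutral core residue
attached to a complete binary tree of branching lysines, so the scaffold
holds ``1 + (2**(g+2) - 1)`` residues and carries ``2**(g+1)`` terminal
lysines. Each terminal lysine exposes two protonated amines
(alpha- and epsilon-NH3+) at normal pH, which fixes the bare charge
``Q_bare = N_end = 2**(g+2)`` (G2 -> 16, G3 -> 32).
Optional glycine spacers are inserted in series on every lysine-lysine edge
(the core-attachment edge carries none), which reproduces the insertion
counts of second-generation 2Gly dendrimers (14 edges x 2 glycines = 28).

Generation numbering convention: "generation g" has ``2**(g+1)`` terminal
NH3+ groups (G2 -> 16, G3 -> 32).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx

from .units import AMINO_ACID_MASS, MASS_CARBON, MASS_PROTON, MASS_WATER

__all__ = [
    "ResidueSpec",
    "DendrimerTopology",
    "StructuralSummary",
    "build_lysine_dendrimer",
    "summarize",
    "fullerene_composition",
    "preset",
    "PRESETS",
]


@dataclass(frozen=True)
class ResidueSpec:
    """One residue bead: name, mass (g/mol), integer charge (e) at normal pH."""

    name: str
    mass: float
    charge: int
    n_protonated_amines: int
    is_branching: bool

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"residue mass must be positive, got {self.mass}")
        if self.charge < 0:
            raise ValueError("dendrimer residues are cationic or neutral")
        if self.n_protonated_amines not in (0, 1, 2):
            raise ValueError("n_protonated_amines must be 0, 1 or 2")


def _lysine(terminal: bool) -> ResidueSpec:
    # interior lysines donate both amines to amide bonds; terminal ones keep
    # alpha- and epsilon-NH3+ protonated
    n_amine = 2 if terminal else 0
    return ResidueSpec(
        name="LYS",
        mass=AMINO_ACID_MASS["LYS"],
        charge=n_amine,
        n_protonated_amines=n_amine,
        is_branching=not terminal,
    )


def _glycine() -> ResidueSpec:
    return ResidueSpec("GLY", AMINO_ACID_MASS["GLY"], 0, 0, False)


def _core(name: str = "ALA") -> ResidueSpec:
    if name not in AMINO_ACID_MASS:
        raise ValueError(f"unknown residue name {name!r}")
    return ResidueSpec(name, AMINO_ACID_MASS[name], 0, 0, False)


@dataclass
class DendrimerTopology:
    """Residue-level tree: nodes are ResidueSpec ids, edges parent->child."""

    residues: dict[int, ResidueSpec]
    edges: list[tuple[int, int]]
    generation_of: dict[int, int]
    core_id: int
    insertion_ids: set[int] = field(default_factory=set)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.residues)
        g.add_edges_from(self.edges)
        return g

    def validate(self) -> None:
        g = self.graph()
        if len(self.edges) != len(self.residues) - 1 or not nx.is_tree(g):
            raise ValueError("topology edges must form a tree")
        for rid in self.terminal_lysine_ids():
            if self.residues[rid].n_protonated_amines != 2:
                raise ValueError(f"terminal lysine {rid} must carry 2 NH3+")
        for rid in self.insertion_ids:
            if g.degree[rid] > 2:
                raise ValueError("insertion residues can never be branch points")

    def terminal_lysine_ids(self) -> list[int]:
        g = self.graph()
        return [
            rid
            for rid, spec in self.residues.items()
            if spec.name == "LYS" and not spec.is_branching and g.degree[rid] == 1
        ]

    def to_json(self) -> str:
        payload = {
            "residues": {str(i): asdict(r) for i, r in self.residues.items()},
            "edges": [list(e) for e in self.edges],
            "generation_of": {str(i): g for i, g in self.generation_of.items()},
            "core_id": self.core_id,
            "insertion_ids": sorted(self.insertion_ids),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DendrimerTopology":
        d = json.loads(text)
        return cls(
            residues={int(i): ResidueSpec(**r) for i, r in d["residues"].items()},
            edges=[tuple(e) for e in d["edges"]],
            generation_of={int(i): g for i, g in d["generation_of"].items()},
            core_id=d["core_id"],
            insertion_ids=set(d["insertion_ids"]),
        )


@dataclass(frozen=True)
class StructuralSummary:
    """Bookkeeping of a dendrimer: mass, bare charge, residue counts."""

    M_d: float
    Q_bare: int
    N_end: int
    N_ins: int
    N_res: int


def build_lysine_dendrimer(
    generation: int, gly_per_spacer: int = 0, core_residue: str = "ALA"
) -> DendrimerTopology:
    """Build the residue tree of a lysine(-glycine) dendrimer.

    Parameters
    ----------
    generation : int
        Dendrimer generation, 1..5. Generation g carries 2**(g+1) terminal
        lysines, hence 2**(g+2) terminal NH3+ groups.
    gly_per_spacer : int
        Number of glycines inserted in series on every lysine-lysine edge
        (0..4). The core-attachment edge carries no insertion.
    core_residue : str
        Residue name of the neutral focal-point residue.
    """
    if not 1 <= generation <= 5:
        raise ValueError(f"generation must be in 1..5, got {generation}")
    if not 0 <= gly_per_spacer <= 4:
        raise ValueError(f"gly_per_spacer must be in 0..4, got {gly_per_spacer}")

    residues: dict[int, ResidueSpec] = {}
    edges: list[tuple[int, int]] = []
    gen_of: dict[int, int] = {}
    next_id = 0

    def new_residue(spec: ResidueSpec, gen: int) -> int:
        nonlocal next_id
        rid = next_id
        next_id += 1
        residues[rid] = spec
        gen_of[rid] = gen
        return rid

    core_id = new_residue(_core(core_residue), 0)
    # lysine tree: root lysine attached to the core, then `generation + 1`
    # doubling levels, so generation g carries 2**(g+1) terminal lysines and
    # 2**(g+2) - 1 scaffold lysines (G2 -> 15 lysines + core = 16 residues)
    level = [new_residue(_lysine(terminal=False), 0)]
    edges.append((core_id, level[0]))
    for depth in range(1, generation + 2):
        terminal = depth == generation + 1
        nxt = []
        for parent in level:
            for _ in range(2):
                child = new_residue(_lysine(terminal), depth)
                edges.append((parent, child))
                nxt.append(child)
        level = nxt

    insertion_ids: set[int] = set()
    if gly_per_spacer > 0:
        expanded: list[tuple[int, int]] = []
        for a, b in edges:
            if a == core_id or b == core_id:
                expanded.append((a, b))
                continue
            prev = a
            for _ in range(gly_per_spacer):
                gid = new_residue(_glycine(), gen_of[b])
                insertion_ids.add(gid)
                expanded.append((prev, gid))
                prev = gid
            expanded.append((prev, b))
        edges = expanded

    topo = DendrimerTopology(residues, edges, gen_of, core_id, insertion_ids)
    topo.validate()
    return topo


def summarize(topology: DendrimerTopology) -> StructuralSummary:
    """Structural bookkeeping computed purely from the residue graph.

    The molecular mass uses condensation-polymer accounting: residue masses,
    minus one water per amide bond, plus one proton per protonated amine.
    """
    topology.validate()
    n_res = len(topology.residues)
    terminal = topology.terminal_lysine_ids()
    n_end = sum(topology.residues[i].n_protonated_amines for i in terminal)
    q_bare = sum(r.charge for r in topology.residues.values())
    n_ins = len(topology.insertion_ids)
    n_amide = len(topology.edges)
    n_protons = sum(r.n_protonated_amines for r in topology.residues.values())
    m_d = (
        sum(r.mass for r in topology.residues.values())
        - n_amide * MASS_WATER
        + n_protons * MASS_PROTON
    )
    return StructuralSummary(M_d=m_d, Q_bare=q_bare, N_end=n_end, N_ins=n_ins, N_res=n_res)


def fullerene_composition(n_carbons: int) -> list[dict]:
    """Particle list of a neutral C60/C70 cage (per-particle charge zero)."""
    if n_carbons not in (60, 70):
        raise ValueError(f"only C60 and C70 are supported, got C{n_carbons}")
    return [
        {"element": "C", "mass": MASS_CARBON, "charge": 0.0}
        for _ in range(n_carbons)
    ]


PRESETS = {
    "lysG2": dict(generation=2, gly_per_spacer=0),
    "lysG3": dict(generation=3, gly_per_spacer=0),
    "lys2Gly": dict(generation=2, gly_per_spacer=2),
}


def preset(name: str) -> DendrimerTopology:
    """Build one of the canonical dendrimers: lysG2, lysG3, lys2Gly."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return build_lysine_dendrimer(**PRESETS[name])
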
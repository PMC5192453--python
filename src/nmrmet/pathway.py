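"""Local metabolic-network mapping: project detected / discriminant
metabolite lists onto a pathway-annotated reaction network and rank the
pathways by how many discriminant metabolites they contain.

The shipped fixture is a small curated network (glycolysis + TCA, starch
hydrolysis, amino-acid and tyrosine metabolism, ...), not a genome-scale
reconstruction; any TSV edge list with the same columns, or an SBML Level 3
file with pathway groups, can be substituted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "Reaction",
    "MetabolicNetwork",
    "PathwayReport",
    "load_network",
    "load_synonyms",
    "default_network_path",
    "map_metabolites",
    "extract_subnetwork",
]


@dataclass(frozen=True)
class Reaction:
    id: str
    substrates: frozenset[str]
    products: frozenset[str]

    @property
    def metabolites(self) -> frozenset[str]:
        return self.substrates | self.products


@dataclass
class MetabolicNetwork:
    """Reactions grouped into (possibly overlapping) pathways."""

    reactions: dict[str, Reaction] = field(default_factory=dict)
    pathways: dict[str, set[str]] = field(default_factory=dict)  # name -> reaction ids
    synonyms: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, rids in self.pathways.items():
            for rid in rids:
                if rid not in self.reactions:
                    raise ValueError(f"pathway {name!r} references unknown reaction {rid!r}")

    @property
    def metabolites(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions.values():
            out |= r.metabolites
        return out

    def pathway_metabolites(self, name: str) -> set[str]:
        out: set[str] = set()
        for rid in self.pathways[name]:
            out |= self.reactions[rid].metabolites
        return out

    def resolve(self, name: str) -> tuple[str, ...]:
        """Resolve an input metabolite name to network node names.

        Case-insensitive; spaces/underscores normalize to hyphens; composite
        aliases (e.g. a glutamine+glutamate pool) may expand to several
        nodes.  Returns an empty tuple when unmatched.
        """
        key = _normalize(name)
        nodes = self.metabolites
        if key in nodes:
            return (key,)
        if key in self.synonyms:
            return tuple(t for t in self.synonyms[key] if t in nodes)
        return ()


def _normalize(name: str) -> str:
    key = str(name).strip().lower().replace("–", "-")
    for ch in (" ", "_"):
        key = key.replace(ch, "-")
    while "--" in key:
        key = key.replace("--", "-")
    return key


def default_network_path() -> Path:
    return Path(str(resources.files("nmrmet").joinpath("data/network.tsv")))


def default_synonyms_path() -> Path:
    return Path(str(resources.files("nmrmet").joinpath("data/synonyms.tsv")))


def load_synonyms(path: str | Path | None = None) -> dict[str, tuple[str, ...]]:
    if path is None:
        path = default_synonyms_path()
    df = pd.read_csv(path, sep="\t")
    out: dict[str, tuple[str, ...]] = {}
    for row in df.itertuples(index=False):
        out[_normalize(row.alias)] = tuple(_normalize(t) for t in str(row.targets).split(";") if t.strip())
    return out


def load_network(path: str | Path | None = None, synonyms: str | Path | None = None) -> MetabolicNetwork:
    """Load a TSV edge list (pathway, reaction, role, metabolite) or an SBML
    Level 3 file.  Every reaction must have at least one substrate and one
    product; violations are rejected with the reaction id."""
    if path is None:
        path = default_network_path()
    path = Path(path)
    syn = load_synonyms(synonyms)
    if path.suffix.lower() in (".xml", ".sbml"):
        return _load_sbml(path, syn)
    df = pd.read_csv(path, sep="\t")
    required = {"pathway", "reaction", "role", "metabolite"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    subs: dict[str, set[str]] = {}
    prods: dict[str, set[str]] = {}
    pathways: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        rid = str(row.reaction)
        met = _normalize(row.metabolite)
        role = str(row.role).strip().lower()
        if role == "substrate":
            subs.setdefault(rid, set()).add(met)
        elif role == "product":
            prods.setdefault(rid, set()).add(met)
        else:
            raise ValueError(f"{path}: unknown role {row.role!r} for reaction {rid!r}")
        pathways.setdefault(str(row.pathway), set()).add(rid)
    reactions: dict[str, Reaction] = {}
    for rid in set(subs) | set(prods):
        if rid not in subs or rid not in prods:
            raise ValueError(f"reaction {rid!r} is dangling (needs both substrates and products)")
        reactions[rid] = Reaction(rid, frozenset(subs[rid]), frozenset(prods[rid]))
    return MetabolicNetwork(reactions=reactions, pathways=pathways, synonyms=syn)


def _load_sbml(path: Path, syn: dict[str, tuple[str, ...]]) -> MetabolicNetwork:
    import cobra.io

    model = cobra.io.read_sbml_model(str(path))
    reactions: dict[str, Reaction] = {}
    for rxn in model.reactions:
        subs = frozenset(_normalize(m.name or m.id) for m, c in rxn.metabolites.items() if c < 0)
        prods = frozenset(_normalize(m.name or m.id) for m, c in rxn.metabolites.items() if c > 0)
        if subs and prods:
            reactions[rxn.id] = Reaction(rxn.id, subs, prods)
    pathways: dict[str, set[str]] = {}
    for group in getattr(model, "groups", []):
        rids = {m.id for m in group.members if m.id in reactions}
        if rids:
            pathways[group.name or group.id] = rids
    if not pathways:
        pathways["all"] = set(reactions)
    return MetabolicNetwork(reactions=reactions, pathways=pathways, synonyms=syn)


@dataclass
class PathwayReport:
    """Per-pathway mapping counts, ranked by discriminant-metabolite count."""

    table: pd.DataFrame  # pathway, n_discriminant, n_detected, size, hypergeom_p
    node_states: dict[str, str]  # metabolite -> {discriminant, detected_only, absent}
    unmatched: list[str]

    @property
    def ranking(self) -> list[str]:
        return self.table["pathway"].tolist()


def _resolve_list(net: MetabolicNetwork, names: Iterable[str]) -> tuple[set[str], list[str]]:
    matched: set[str] = set()
    unmatched: list[str] = []
    for name in names:
        nodes = net.resolve(name)
        if nodes:
            matched.update(nodes)
        else:
            unmatched.append(str(name))
    return matched, unmatched


def map_metabolites(
    net: MetabolicNetwork,
    detected: Iterable[str],
    discriminant: Iterable[str],
) -> PathwayReport:
    """Project the detected and discriminant metabolite lists onto the network.

    Counts are per *input* metabolite: a composite entry (e.g. a combined
    glutamine/glutamate pool) counts once however many nodes it resolves to.
    Pathways are ranked by discriminant count, ties by detected count, then
    by name.  A supplementary hypergeometric enrichment p-value is reported
    but is not the ranking key.  Unmatched names are reported, not fatal.
    """
    detected = [str(n) for n in detected]
    discriminant = [str(n) for n in discriminant]
    # discriminant metabolites are detected by definition
    det_names = list(dict.fromkeys(detected + [d for d in discriminant if d not in detected]))
    resolved = {name: set(net.resolve(name)) for name in det_names}
    unmatched = sorted(name for name, nodes in resolved.items() if not nodes)
    if unmatched and not any(resolved.values()):
        warnings.warn("no input metabolite matched any network node")
    disc_names = [n for n in discriminant if resolved.get(n)]
    matched_names = [n for n in det_names if resolved[n]]
    disc_nodes = set().union(*(resolved[n] for n in disc_names)) if disc_names else set()
    detected_nodes = set().union(*(resolved[n] for n in matched_names)) if matched_names else set()
    all_nodes = net.metabolites
    rows = []
    for name in net.pathways:
        members = net.pathway_metabolites(name)
        in_pathway = [n for n in matched_names if resolved[n] & members]
        n_det = len(in_pathway)
        n_disc = sum(1 for n in in_pathway if n in disc_names)
        # enrichment among the matched detected metabolites
        p = float(
            stats.hypergeom.sf(n_disc - 1, len(matched_names), len(disc_names), n_det)
        )
        rows.append(
            {
                "pathway": name,
                "n_discriminant": n_disc,
                "n_detected": n_det,
                "size": len(members),
                "hypergeom_p": p,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        by=["n_discriminant", "n_detected", "pathway"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    node_states = {}
    for node in sorted(all_nodes):
        if node in disc_nodes:
            node_states[node] = "discriminant"
        elif node in detected_nodes:
            node_states[node] = "detected_only"
        else:
            node_states[node] = "absent"
    return PathwayReport(table=table, node_states=node_states, unmatched=unmatched)


def extract_subnetwork(net: MetabolicNetwork, metabolites: Sequence[str]) -> MetabolicNetwork:
    """Minimal sub-network: all reactions touching any listed metabolite,
    with their full substrate/product sets, and the pathway cover restricted
    to the kept reactions."""
    if not metabolites:
        raise ValueError("metabolite list must be non-empty")
    targets, _ = _resolve_list(net, metabolites)
    kept = {rid: r for rid, r in net.reactions.items() if r.metabolites & targets}
    if not kept:
        warnings.warn("no reaction touches any listed metabolite; empty sub-network")
    pathways = {
        name: rids & set(kept)
        for name, rids in net.pathways.items()
        if rids & set(kept)
    }
    return MetabolicNetwork(reactions=kept, pathways=pathways, synonyms=net.synonyms)


def to_networkx(net: MetabolicNetwork):
    """Bipartite reaction/metabolite graph for rendering or analysis."""
    import networkx as nx

    g = nx.Graph()
    for rid, r in net.reactions.items():
        g.add_node(rid, kind="reaction")
        for m in r.substrates:
            g.add_node(m, kind="metabolite")
            g.add_edge(m, rid, role="substrate")
        for m in r.products:
            g.add_node(m, kind="metabolite")
            g.add_edge(rid, m, role="product")
    return g


def write_dot(net: MetabolicNetwork, node_states: Mapping[str, str], path: str | Path) -> None:
    """DOT rendering with the discriminant / detected-only coloring."""
    colors = {"discriminant": "gold", "detected_only": "lightblue", "absent": "white"}
    lines = ["graph metabolic {", "  node [style=filled];"]
    for rid, r in net.reactions.items():
        lines.append(f'  "{rid}" [shape=box, fillcolor=gray90];')
        for m in r.metabolites:
            state = node_states.get(m, "absent")
            lines.append(f'  "{m}" [shape=ellipse, fillcolor={colors[state]}];')
            lines.append(f'  "{m}" -- "{rid}";')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
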
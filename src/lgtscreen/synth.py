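"""Synthetic inputs with planted truth for every pipeline stage.

Three generators:

* :func:`make_gene_tree` — gene trees with a planted vertical or LGT
  history for a focal archaeon (and optionally its companion genus),
  together with the classification the screen should recover;
* :func:`make_cds_set` — coding sequences whose codons are drawn from a
  mixture of host and donor codon frequencies, the mixing weight alpha
  modelling amelioration (alpha = 1: fully host-adapted);
* :func:`evolve_pam` — presence/absence matrices evolved by gain/loss
  events along a species tree, with the event list as truth.

All generators are deterministic under a fixed seed and emit truth
objects the test-suite consumes directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .ancestral_content import PresenceAbsenceMatrix, label_nodes
from .codon_metrics import SYNONYMS, CodingSequence
from .lgt_classify import (
    A_TO_B,
    B_TO_A,
    E_TO_A,
    LGT_BACTERIAL,
    LGT_EUKARYOTE,
    LGT_NESTED,
    NON_LGT,
    NOT_APPLICABLE,
    ScreenConfig,
    TreeClassification,
    UNDETERMINED,
    support_tier,
)
from .trees import AnnotatedGeneTree, TaxonRecord, annotate, parse_newick

SCENARIOS = (
    "vertical",
    "recent_bacterial_lgt",
    "ancient_pre_divergence_lgt",
    "eukaryotic_lgt",
    "archaea_export",
)

#: bacterial phylum -> representative genus, mirroring gut-community donors
PHYLUM_PALETTE = (
    ("Firmicutes", "Clostridium"),
    ("Bacteroidetes", "Bacteroides"),
    ("Proteobacteria", "Escherichia"),
    ("Actinobacteria", "Bifidobacterium"),
    ("Fusobacteria", "Fusobacterium"),
    ("Spirochaetes", "Treponema"),
    ("Verrucomicrobia", "Akkermansia"),
    ("Cyanobacteria", "Synechococcus"),
)

ARCHAEA_PALETTE = (
    ("Methanosarcina", "Euryarchaeota"),
    ("Methanococcus", "Euryarchaeota"),
    ("Methanothermobacter", "Euryarchaeota"),
    ("Haloferax", "Euryarchaeota"),
    ("Sulfolobus", "Crenarchaeota"),
    ("Thermococcus", "Euryarchaeota"),
)

EUKARYOTE_PALETTE = (
    ("Saccharomyces", "Ascomycota"),
    ("Dictyostelium", "Amoebozoa"),
    ("Arabidopsis", "Streptophyta"),
    ("Homo", "Chordata"),
)


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one planted gene-tree scenario."""

    scenario: str
    n_bacteria: int = 6
    n_bacterial_phyla: int = 3
    n_archaea: int = 4
    n_eukaryotes: int = 3
    support_mean: float = 75.0
    support_sd: float = 15.0
    companions: tuple[str, ...] = ("smithii", "ruminantium")
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for name in ("n_bacteria", "n_bacterial_phyla", "n_archaea", "n_eukaryotes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        needs = {
            "vertical": self.n_archaea >= 2 and self.n_bacteria >= 2,
            "recent_bacterial_lgt": self.n_bacteria >= 3
            and self.n_bacterial_phyla >= 3
            and self.n_archaea >= 1,
            "ancient_pre_divergence_lgt": self.n_bacteria >= 4
            and self.n_bacterial_phyla >= 3
            and self.n_archaea >= 1
            and len(self.companions) >= 1,
            "eukaryotic_lgt": self.n_eukaryotes >= 2 and self.n_archaea >= 1,
            "archaea_export": self.n_bacteria >= 1 and self.n_archaea >= 3,
        }
        if not needs[self.scenario]:
            raise ValueError(f"infeasible spec for scenario {self.scenario!r}")
        if self.n_bacterial_phyla > len(PHYLUM_PALETTE):
            raise ValueError("n_bacterial_phyla exceeds phylum palette")


def _taxa_pools(spec: ScenarioSpec) -> dict[str, list[TaxonRecord]]:
    bacteria = []
    for i in range(spec.n_bacteria):
        phylum, genus = PHYLUM_PALETTE[i % spec.n_bacterial_phyla]
        bacteria.append(
            TaxonRecord(f"bac{i:02d}", f"{genus} sp{i}", genus, phylum, "Bacteria")
        )
    archaea = []
    for i in range(spec.n_archaea):
        genus, phylum = ARCHAEA_PALETTE[i % len(ARCHAEA_PALETTE)]
        archaea.append(
            TaxonRecord(f"arc{i:02d}", f"{genus} sp{i}", genus, phylum, "Archaea")
        )
    euks = []
    for i in range(spec.n_eukaryotes):
        genus, phylum = EUKARYOTE_PALETTE[i % len(EUKARYOTE_PALETTE)]
        euks.append(
            TaxonRecord(f"euk{i:02d}", f"{genus} sp{i}", genus, phylum, "Eukaryota")
        )
    focal = TaxonRecord(
        "Msta", "Methanosphaera stadtmanae", "Methanosphaera", "Euryarchaeota", "Archaea"
    )
    companions = []
    for short in spec.companions:
        companions.append(
            TaxonRecord(
                f"M{short[:3]}",
                f"Methanobrevibacter {short}",
                "Methanobrevibacter",
                "Euryarchaeota",
                "Archaea",
            )
        )
    return {
        "bacteria": bacteria,
        "archaea": archaea,
        "eukaryotes": euks,
        "focal": [focal],
        "companions": companions,
    }


def _el(rng) -> str:
    return f"{rng.uniform(0.05, 0.15):.4f}"


def _hs(rng) -> int:
    """High support for non-inspected edges."""
    return int(rng.integers(90, 101))


def _clade(records, rng) -> str:
    """Random ladder Newick over the records, high supports throughout."""
    if len(records) == 1:
        return f"{records[0].leaf_id}:{_el(rng)}"
    inner = f"({records[0].leaf_id}:{_el(rng)},{records[1].leaf_id}:{_el(rng)}){_hs(rng)}"
    sub = f"{inner}:{_el(rng)}"
    for rec in records[2:]:
        sub = f"({sub},{rec.leaf_id}:{_el(rng)}){_hs(rng)}:{_el(rng)}"
    return sub


def _planted_support(spec: ScenarioSpec, rng) -> int:
    return int(np.clip(round(rng.normal(spec.support_mean, spec.support_sd)), 0, 100))


def make_gene_tree(
    spec: ScenarioSpec, config: ScreenConfig = ScreenConfig(), gene_id: str = ""
) -> tuple[AnnotatedGeneTree, TreeClassification]:
    """Build a gene tree with a planted history and its expected verdict.

    The inspected branch (focal clade vs its sister) carries a bootstrap
    support drawn from a truncated normal; all other edges get high
    support. The tree is laid out so that midpoint rooting separates the
    focal side from a distant outgroup clade.
    """
    rng = np.random.default_rng(spec.seed)
    pools = _taxa_pools(spec)
    focal = pools["focal"][0]
    support = _planted_support(spec, rng)
    gene_id = gene_id or f"synth_{spec.scenario}_{spec.seed}"

    expected = TreeClassification(gene_id=gene_id)
    used: list[TaxonRecord] = [focal]

    if spec.scenario == "vertical":
        a1, a2 = pools["archaea"][:2]
        rest_arch = pools["archaea"][2:]
        used += [a1, a2] + rest_arch + pools["bacteria"]
        sister = f"({a1.leaf_id}:{_el(rng)},{a2.leaf_id}:{_el(rng)}){_hs(rng)}:{_el(rng)}"
        ingroup = f"({focal.leaf_id}:{_el(rng)},{sister}){_hs(rng)}"
        if rest_arch:
            ingroup = f"({ingroup}:{_el(rng)},{_clade(rest_arch, rng)}){_hs(rng)}"
        outgroup = f"({_clade(pools['bacteria'], rng)}){_hs(rng)}"
        expected = TreeClassification(
            gene_id=gene_id, status=NON_LGT, direction=NOT_APPLICABLE
        )

    elif spec.scenario == "recent_bacterial_lgt":
        bacteria = pools["bacteria"]
        b1, rest = bacteria[0], bacteria[1:]
        half = max(1, len(rest) // 2)
        g2, g3 = rest[:half], rest[half:]
        used += bacteria + pools["archaea"]
        ingroup = f"({focal.leaf_id}:{_el(rng)},{b1.leaf_id}:{_el(rng)}){support}"
        ingroup = f"({ingroup}:{_el(rng)},{_clade(g2, rng)}){_hs(rng)}"
        if g3:
            ingroup = f"({ingroup}:{_el(rng)},{_clade(g3, rng)}){_hs(rng)}"
        outgroup = f"({_clade(pools['archaea'], rng)}){_hs(rng)}"
        expected = TreeClassification(
            gene_id=gene_id,
            status=LGT_BACTERIAL,
            direction=B_TO_A,
            inspected_branch_support=support,
            support_tier=support_tier(support, config),
            donor_phylum=b1.phylum,
        )

    elif spec.scenario == "ancient_pre_divergence_lgt":
        bacteria = pools["bacteria"]
        # the focal+companion clade's sister must itself span >= 3 phyla
        n_inner = max(spec.n_bacterial_phyla, len(bacteria) - 1)
        inner, outer = bacteria[:n_inner], bacteria[n_inner:]
        if not outer:
            inner, outer = bacteria[:-1], bacteria[-1:]
        comps = pools["companions"]
        used += comps + bacteria + pools["archaea"]
        comp_clade = (
            f"{comps[0].leaf_id}:{_el(rng)}"
            if len(comps) == 1
            else f"({comps[0].leaf_id}:{_el(rng)},{comps[1].leaf_id}:{_el(rng)}){_hs(rng)}:{_el(rng)}"
        )
        fc = f"({focal.leaf_id}:{_el(rng)},{comp_clade}){support}"
        ingroup = f"({fc}:{_el(rng)},{_clade(inner, rng)}){_hs(rng)}"
        ingroup = f"({ingroup}:{_el(rng)},{_clade(outer, rng)}){_hs(rng)}"
        outgroup = f"({_clade(pools['archaea'], rng)}){_hs(rng)}"
        label = "both" if len(comps) >= 2 else f"Methanobrevibacter {spec.companions[0]}".split()[-1].lower()
        expected = TreeClassification(
            gene_id=gene_id,
            status=LGT_NESTED,
            companion_present=label,
            direction=B_TO_A,
            inspected_branch_support=support,
            support_tier=support_tier(support, config),
            donor_phylum=UNDETERMINED
            if len({r.phylum for r in inner}) > 1
            else inner[0].phylum,
        )

    elif spec.scenario == "eukaryotic_lgt":
        euks = pools["eukaryotes"]
        e1, rest = euks[0], euks[1:]
        used += euks + pools["archaea"]
        ingroup = f"({focal.leaf_id}:{_el(rng)},{e1.leaf_id}:{_el(rng)}){support}"
        ingroup = f"({ingroup}:{_el(rng)},{_clade(rest, rng)}){_hs(rng)}"
        outgroup = f"({_clade(pools['archaea'], rng)}){_hs(rng)}"
        expected = TreeClassification(
            gene_id=gene_id,
            status=LGT_EUKARYOTE,
            direction=E_TO_A,
            inspected_branch_support=support,
            support_tier=support_tier(support, config),
            donor_phylum=e1.phylum or UNDETERMINED,
        )

    else:  # archaea_export
        b1 = pools["bacteria"][0]
        archaea = pools["archaea"]
        a1, a2, out_arch = archaea[0], archaea[1], archaea[2:]
        used += [b1, a1, a2] + out_arch
        ingroup = f"({focal.leaf_id}:{_el(rng)},{b1.leaf_id}:{_el(rng)}){support}"
        ingroup = f"({ingroup}:{_el(rng)},{a1.leaf_id}:{_el(rng)}){_hs(rng)}"
        ingroup = f"({ingroup}:{_el(rng)},{a2.leaf_id}:{_el(rng)}){_hs(rng)}"
        outgroup = f"({_clade(out_arch, rng)}){_hs(rng)}"
        expected = TreeClassification(
            gene_id=gene_id,
            status=LGT_BACTERIAL,
            direction=A_TO_B,
            inspected_branch_support=support,
            support_tier=support_tier(support, config),
            donor_phylum=b1.phylum,
        )

    newick = f"({ingroup}:2.0,{outgroup}:2.0);"
    gtree = parse_newick(newick, gene_id=gene_id)
    taxonomy = {r.leaf_id: r for r in used}
    annotate(gtree, taxonomy, strict=True)
    return gtree, expected


def make_scenario_batch(
    n: int, seed: int, config: ScreenConfig = ScreenConfig()
) -> list[tuple[AnnotatedGeneTree, TreeClassification]]:
    """A deterministic round-robin batch over all five scenarios."""
    out = []
    for i in range(n):
        scenario = SCENARIOS[i % len(SCENARIOS)]
        spec = ScenarioSpec(scenario=scenario, seed=seed + i)
        out.append(make_gene_tree(spec, config, gene_id=f"g{i:04d}"))
    return out


# ---------------------------------------------------------------------------
# coding sequences with tunable amelioration


#: amino acids with a synonymous choice (the informative ones for CAI/ENC)
MULTI_CODON_AA = tuple(sorted(aa for aa, cods in SYNONYMS.items() if len(cods) > 1))


def uniform_codon_freqs() -> dict[str, float]:
    """Uniform synonymous usage (ENC -> 61 in long genes)."""
    freqs = {}
    for aa, codons in SYNONYMS.items():
        for c in codons:
            freqs[c] = 1.0 / len(codons)
    return freqs


def biased_codon_freqs(bias: float, seed: int) -> dict[str, float]:
    """Codon frequencies interpolating uniform (bias=0) to one preferred
    codon per amino acid (bias=1); the preferred codon is seed-chosen."""
    if not 0 <= bias <= 1:
        raise ValueError("bias must be in [0, 1]")
    rng = np.random.default_rng(seed)
    freqs = {}
    for aa in sorted(SYNONYMS):
        codons = sorted(SYNONYMS[aa])
        preferred = codons[rng.integers(len(codons))]
        for c in codons:
            uniform = 1.0 / len(codons)
            freqs[c] = bias * (1.0 if c == preferred else 0.0) + (1 - bias) * uniform
    return freqs


@dataclass(frozen=True)
class AmeliorationSpec:
    """Mixture model of codon amelioration.

    Each codon of each gene is drawn, within its amino acid, from
    ``alpha * host + (1 - alpha) * donor`` codon frequencies: alpha = 0 is
    a fresh transfer still using donor codons, alpha = 1 a fully
    ameliorated (host-like) gene.
    """

    host_codon_freqs: dict[str, float]
    donor_codon_freqs: dict[str, float]
    alpha: float
    n_genes: int = 50
    gene_length_codons: int = 300
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.n_genes < 1 or self.gene_length_codons < 1:
            raise ValueError("n_genes and gene_length_codons must be positive")


def _mixture_tables(spec: AmeliorationSpec) -> dict[str, tuple[list[str], np.ndarray]]:
    tables = {}
    for aa in MULTI_CODON_AA:
        codons = sorted(SYNONYMS[aa])
        h = np.array([spec.host_codon_freqs.get(c, 0.0) for c in codons])
        d = np.array([spec.donor_codon_freqs.get(c, 0.0) for c in codons])
        if h.sum() <= 0 or d.sum() <= 0:
            raise ValueError(f"no codon frequencies supplied for amino acid {aa}")
        p = spec.alpha * h / h.sum() + (1 - spec.alpha) * d / d.sum()
        tables[aa] = (codons, p / p.sum())
    return tables


def make_cds_set(spec: AmeliorationSpec) -> tuple[list[CodingSequence], pd.DataFrame]:
    """Sample coding sequences from the amelioration mixture.

    Amino acids are drawn uniformly over the multi-codon amino acids;
    the truth table records the alpha of every gene.
    """
    rng = np.random.default_rng(spec.seed)
    tables = _mixture_tables(spec)
    seqs, rows = [], []
    for g in range(spec.n_genes):
        aas = rng.choice(MULTI_CODON_AA, size=spec.gene_length_codons)
        codons = []
        for aa in aas:
            cods, p = tables[aa]
            codons.append(cods[rng.choice(len(cods), p=p)])
        gene_id = f"gene{g:04d}"
        seqs.append(CodingSequence.from_string(gene_id, "".join(codons)))
        rows.append({"gene_id": gene_id, "alpha": spec.alpha})
    return seqs, pd.DataFrame(rows, columns=["gene_id", "alpha"])


def write_fasta(seqs, path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.gene_id}\n")
            for i in range(0, len(s.nucleotides), 70):
                fh.write(s.nucleotides[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# presence/absence evolution


@dataclass
class SimulatedPAM:
    matrix: PresenceAbsenceMatrix
    events: pd.DataFrame  # columns: branch, family, event
    node_states: dict[str, frozenset] = field(default_factory=dict)


def evolve_pam(
    tree: dendropy.Tree,
    n_families: int,
    gain_rate: float,
    loss_rate: float,
    max_events_per_family: int | None = None,
    seed: int = 0,
    root_presence_prob: float = 0.5,
) -> SimulatedPAM:
    """Evolve binary families down a rooted species tree.

    On each branch a gain (if absent) occurs with probability
    ``1 - exp(-gain_rate * length)`` and a loss (if present) with the
    analogous loss probability; per-family event counts can be capped.
    Families that end up absent from every leaf are redrawn so the output
    matrix satisfies its no-all-absent invariant.

    Events are never placed on the two branches incident to the root: an
    event there is unidentifiable from leaf data (a loss on one root-child
    branch produces the same leaf pattern as a gain on its sibling), so
    planted histories stay recoverable by parsimony.
    """
    if gain_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    label_nodes(tree)
    species = sorted(lf.taxon.label for lf in tree.leaf_node_iter())

    family_ids = [f"FAM{i:04d}" for i in range(n_families)]
    rows, all_events = [], []
    node_present: dict[str, set] = {nd.label: set() for nd in tree.preorder_node_iter()}

    for family in family_ids:
        for _attempt in range(200):
            states, events = _evolve_family(
                tree, gain_rate, loss_rate, max_events_per_family, rng,
                root_presence_prob,
            )
            leaf_states = {
                lf.taxon.label: states[lf.label] for lf in tree.leaf_node_iter()
            }
            if any(leaf_states.values()):
                break
        else:
            raise RuntimeError(
                "could not simulate an observable family; rates too extreme"
            )
        rows.append([leaf_states[s] for s in species])
        for label, state in states.items():
            if state:
                node_present[label].add(family)
        all_events.extend((branch, family, kind) for branch, kind in events)

    matrix = PresenceAbsenceMatrix(family_ids, species, np.array(rows, dtype=int))
    events_df = pd.DataFrame(all_events, columns=["branch", "family", "event"])
    return SimulatedPAM(
        matrix=matrix,
        events=events_df,
        node_states={k: frozenset(v) for k, v in node_present.items()},
    )


def _evolve_family(tree, gain_rate, loss_rate, max_events, rng, root_presence_prob):
    states: dict[str, int] = {}
    events: list[tuple[str, str]] = []
    root = tree.seed_node
    states[root.label] = int(rng.random() < root_presence_prob)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_state = states[node.parent_node.label]
        length = node.edge.length if node.edge.length is not None else 1.0
        state = parent_state
        capped = (max_events is not None and len(events) >= max_events) or (
            node.parent_node is root  # root-incident events are unidentifiable
        )
        if not capped:
            if parent_state == 0 and gain_rate > 0:
                if rng.random() < 1.0 - np.exp(-gain_rate * length):
                    state = 1
                    events.append((node.label, "gain"))
            elif parent_state == 1 and loss_rate > 0:
                if rng.random() < 1.0 - np.exp(-loss_rate * length):
                    state = 0
                    events.append((node.label, "loss"))
        states[node.label] = state
    return states, events


def enumerate_unrooted_topologies(leaves: list[str]) -> list[tuple]:
    """Every unrooted binary topology over the leaf labels (3 <= n <= ~7).

    Trees are nested tuples whose outermost tuple is the central
    trifurcation; counts follow (2n-5)!!: 1, 3, 15, 105 for n = 3..6.
    Use :func:`topology_newick` to serialize with branch lengths.
    """
    if len(leaves) < 3:
        raise ValueError("need at least 3 leaves")

    def variants(sub, x):
        yield (sub, x)  # insert on the edge above this subtree
        if isinstance(sub, tuple):
            for i, child in enumerate(sub):
                for v in variants(child, x):
                    yield sub[:i] + (v,) + sub[i + 1:]

    trees = [tuple(leaves[:3])]
    for x in leaves[3:]:
        grown = []
        for t in trees:
            for i, child in enumerate(t):
                for v in variants(child, x):
                    grown.append(t[:i] + (v,) + t[i + 1:])
        trees = grown
    return trees


def topology_newick(topology: tuple, rng, min_len: float = 0.1,
                    max_len: float = 1.0) -> str:
    """Serialize a nested-tuple topology with random branch lengths."""

    def render(sub):
        if isinstance(sub, str):
            return f"{sub}:{rng.uniform(min_len, max_len):.6f}"
        inner = ",".join(render(ch) for ch in sub)
        return f"({inner}):{rng.uniform(min_len, max_len):.6f}"

    inner = ",".join(render(ch) for ch in topology)
    return f"({inner});"


def random_species_tree(n_species: int, seed: int, prefix: str = "sp") -> dendropy.Tree:
    """A random rooted binary species tree with exponential branch lengths."""
    rng = np.random.default_rng(seed)
    taxa = [f"{prefix}{i:02d}" for i in range(n_species)]
    ns = dendropy.TaxonNamespace()
    nodes = []
    for t in taxa:
        node = dendropy.Node(taxon=ns.new_taxon(label=t))
        node.edge.length = float(rng.exponential(0.3))
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        parent.edge.length = float(rng.exponential(0.3))
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    return tree
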
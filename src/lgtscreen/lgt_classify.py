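"""Per-gene-tree lateral-gene-transfer classification.

A gene tree of a focal archaeon is screened by asking what the focal
leaf's closest phylogenetic neighbor (its sister group after rooting) is:

* an archaeal group other than the companion genus -> vertical (non-LGT);
* a purely bacterial group -> LGT candidate with a bacterial neighbor;
* purely the companion genus -> the focal + companion clade is tested for
  nesting inside a bacterial clade (an ancient, pre-divergence transfer);
* a purely eukaryotic group -> LGT candidate with a eukaryotic neighbor;
* a mixed-domain group -> conservatively non-LGT, flagged for review.

A *bacterial clade* is a clade whose members are all bacteria spanning at
least ``min_bacterial_phyla`` distinct phyla — enough phyletic diversity
to witness a genuinely bacterial origin rather than a stray mislabeled
leaf. Transfer direction, a rescue rule for trees where the focal and
companion genera are the only archaea present, bootstrap tiering of the
inspected branch, and donor-phylum attribution follow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import dendropy

from .trees import AnnotatedGeneTree, TaxonRecord, midpoint_root

logger = logging.getLogger(__name__)


# status values
NON_LGT = "non_LGT"
LGT_BACTERIAL = "LGT_bacterial_neighbor"
LGT_NESTED = "LGT_nested_methanogen_pair"
LGT_EUKARYOTE = "LGT_eukaryote_neighbor"
STATUSES = (NON_LGT, LGT_BACTERIAL, LGT_NESTED, LGT_EUKARYOTE)

# directions
B_TO_A = "bacteria_to_archaea"
A_TO_B = "archaea_to_bacteria"
E_TO_A = "eukarya_to_archaea"
UNKNOWN = "unknown"
NOT_APPLICABLE = "not_applicable"
DIRECTIONS = (B_TO_A, A_TO_B, E_TO_A, UNKNOWN, NOT_APPLICABLE)

# support tiers
TIER_HIGH = "high"
TIER_MODERATE = "moderate"
TIER_LOW = "low"
TIER_ABSENT = "absent"

UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class ScreenConfig:
    """Screen parameters.

    ``focal_species`` is the organism whose genome is screened;
    ``companion_genus`` is its nearest archaeal relative, whose presence as
    sister triggers the nested (pre-divergence transfer) test. The tier
    bounds implement high (> ``tier_high_gt``), moderate
    (``tier_moderate_low``..``tier_moderate_high``) and low (below the
    moderate band, including the configurable boundary value 50).
    """

    focal_species: str = "Methanosphaera stadtmanae"
    companion_genus: str = "Methanobrevibacter"
    companion_species: tuple[str, ...] = (
        "Methanobrevibacter smithii",
        "Methanobrevibacter ruminantium",
    )
    min_bacterial_phyla: int = 3
    tier_high_gt: int = 70
    tier_moderate_low: int = 51
    tier_moderate_high: int = 70
    # an archaea->bacteria export call requires a small bacterial insert ...
    max_export_sister_leaves: int = 3
    # ... enclosed by a broad archaeal context (distinct non-focal genera)
    min_archaeal_context_genera: int = 2
    rooting: str = "midpoint"  # or "as-provided"
    max_nesting_levels: int | None = None  # unbounded ascent by default

    def __post_init__(self):
        if self.min_bacterial_phyla < 1:
            raise ValueError("min_bacterial_phyla must be >= 1")
        if not (self.tier_moderate_low <= self.tier_moderate_high <= 100):
            raise ValueError("tier bounds must be ordered")
        if self.rooting not in ("midpoint", "as-provided"):
            raise ValueError(f"unknown rooting mode {self.rooting!r}")


@dataclass
class TreeClassification:
    """Verdict for one gene tree (or one focal paralog within it)."""

    gene_id: str
    status: str = NON_LGT
    companion_present: str = "none"
    direction: str = NOT_APPLICABLE
    only_archaea_rescue: bool = False
    inspected_branch_support: int | None = None
    support_tier: str = TIER_ABSENT
    donor_phylum: str = UNDETERMINED
    # the raw observation behind the rescue rule: focal + companion are the
    # only archaea anywhere on the tree (independent of direction)
    only_archaea: bool = False
    review_notes: list[str] = field(default_factory=list)
    per_leaf: list["TreeClassification"] = field(default_factory=list)
    root_side_domains: tuple[tuple[str, ...], tuple[str, ...]] | None = None

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if (self.direction == NOT_APPLICABLE) != (self.status == NON_LGT):
            raise ValueError(
                "direction must be not_applicable exactly when status is non_LGT"
            )
        if self.only_archaea_rescue and self.status == NON_LGT:
            raise ValueError("only_archaea_rescue requires an LGT status")

    @property
    def is_lgt(self) -> bool:
        return self.status != NON_LGT


def support_tier(support: int | None, config: ScreenConfig = ScreenConfig()) -> str:
    """Bin a bootstrap percentage into high / moderate / low / absent."""
    if support is None:
        return TIER_ABSENT
    if not (0 <= support <= 100):
        raise ValueError(f"support {support} outside [0, 100]")
    if support > config.tier_high_gt:
        return TIER_HIGH
    if config.tier_moderate_low <= support <= config.tier_moderate_high:
        return TIER_MODERATE
    return TIER_LOW


def is_bacterial_clade(records, config: ScreenConfig = ScreenConfig()) -> bool:
    """True iff all members are bacteria spanning >= min_bacterial_phyla phyla."""
    records = list(records)
    if not records:
        raise ValueError("empty leaf set")
    if any(r.domain != "Bacteria" for r in records):
        return False
    return len({r.phylum for r in records}) >= config.min_bacterial_phyla


# ---------------------------------------------------------------------------
# tree helpers


def _leaf_records(gtree: AnnotatedGeneTree, node: dendropy.Node) -> list[TaxonRecord]:
    out = []
    for lf in node.leaf_iter():
        label = lf.taxon.label
        if label not in gtree.annotations:
            raise KeyError(f"leaf {label!r} has no taxonomy annotation")
        out.append(gtree.annotations[label])
    return out


def _focal_leaves(gtree: AnnotatedGeneTree, config: ScreenConfig) -> list[dendropy.Node]:
    focal = [
        lf
        for lf in gtree.tree.leaf_node_iter()
        if gtree.annotations.get(lf.taxon.label)
        and gtree.annotations[lf.taxon.label].species == config.focal_species
    ]
    return sorted(focal, key=lambda lf: lf.taxon.label)


def closest_neighbor_group(
    gtree: AnnotatedGeneTree, config: ScreenConfig = ScreenConfig()
) -> set[str]:
    """Leaf ids of the focal leaf's sister group on the rooted tree.

    With several focal paralogs the sister of the alphabetically first
    focal leaf is returned; :func:`classify_tree` examines every paralog.
    """
    focal = _focal_leaves(gtree, config)
    if not focal:
        raise ValueError("focal taxon not in tree")
    return {r.leaf_id for r in _sister_records(gtree, focal[0])}


def _sister_records(gtree: AnnotatedGeneTree, node: dendropy.Node) -> list[TaxonRecord]:
    parent = node.parent_node
    if parent is None:
        raise ValueError("focal leaf is the root; tree is not properly rooted")
    own = {lf.taxon.label for lf in node.leaf_iter()}
    return [
        r for r in _leaf_records(gtree, parent) if r.leaf_id not in own
    ]


def _companion_label(records, config: ScreenConfig) -> str:
    """Which companion species occur in a leaf group: none / <species> / both."""
    present = [
        sp for sp in config.companion_species
        if any(r.species == sp for r in records)
    ]
    if not present:
        return "none"
    if len(present) >= 2:
        return "both"
    return present[0].split()[-1].lower()


def classify_tree(
    gtree: AnnotatedGeneTree, config: ScreenConfig = ScreenConfig()
) -> TreeClassification:
    """Classify one annotated gene tree.

    Midpoint-roots the tree first unless ``config.rooting`` is
    "as-provided". Every focal paralog is classified independently; the
    per-gene verdict is LGT if any copy is LGT, with per-leaf detail kept
    in ``per_leaf``.
    """
    if not gtree.is_fully_annotated():
        missing = [lid for lid in gtree.leaf_ids if lid not in gtree.annotations]
        raise KeyError(f"unannotated leaves: {sorted(missing)}")
    if config.rooting == "midpoint":
        midpoint_root(gtree)
    focal = _focal_leaves(gtree, config)
    if not focal:
        raise ValueError("focal taxon not in tree")

    per_leaf = [_classify_focal_leaf(gtree, leaf, config) for leaf in focal]
    lgt_hits = [c for c in per_leaf if c.is_lgt]
    verdict = replace(lgt_hits[0]) if lgt_hits else replace(per_leaf[0])
    verdict.per_leaf = per_leaf if len(per_leaf) > 1 else []
    verdict.root_side_domains = _root_side_domains(gtree)
    return verdict


def _root_side_domains(gtree):
    root = gtree.tree.seed_node
    sides = []
    for child in root.child_nodes():
        doms = tuple(sorted({r.domain for r in _leaf_records(gtree, child)}))
        sides.append(doms)
    while len(sides) < 2:
        sides.append(())
    return tuple(sides[:2])


def _classify_focal_leaf(
    gtree: AnnotatedGeneTree, leaf: dendropy.Node, config: ScreenConfig
) -> TreeClassification:
    gene_id = gtree.gene_id
    sister = _sister_records(gtree, leaf)
    domains = {r.domain for r in sister}
    notes: list[str] = []

    focal_clade = leaf  # smallest clade whose neighborhood we inspect
    status = NON_LGT
    neighbor: list[TaxonRecord] = sister

    all_companion = sister and all(
        r.domain == "Archaea" and r.genus == config.companion_genus for r in sister
    )

    if domains == {"Archaea"} and not all_companion:
        status = NON_LGT
    elif domains == {"Bacteria"}:
        status = LGT_BACTERIAL
    elif all_companion:
        # ascend while the running clade's sister is still pure companion,
        # yielding the smallest clade holding focal + companion leaves
        clade = leaf.parent_node
        while clade.parent_node is not None:
            rest = _other_side(gtree, clade)
            if rest and all(
                r.domain == "Archaea" and r.genus == config.companion_genus
                for r in rest
            ):
                clade = clade.parent_node
                continue
            break
        rest = _other_side(gtree, clade)
        if rest and is_bacterial_clade(rest, config):
            status = LGT_NESTED
            focal_clade = clade
            neighbor = rest
        else:
            status = NON_LGT
            notes.append("companion sister but enclosure not a bacterial clade")
    elif domains == {"Eukaryota"}:
        status = LGT_EUKARYOTE
    else:
        status = NON_LGT
        notes.append(f"mixed-domain sister group {sorted(domains)}; review")

    cls = TreeClassification(
        gene_id=gene_id,
        status=status,
        direction=NOT_APPLICABLE if status == NON_LGT else UNKNOWN,
        review_notes=notes,
    )
    cls.only_archaea = _only_focal_and_companion_archaea(gtree, config)
    cls.companion_present = _companion_label(sister, config)

    if status == NON_LGT:
        return cls

    # inspected branch: the edge separating the focal lineage from the rest
    # of the tree. For a focal+companion clade that is the clade's own
    # subtending edge; for a bare focal leaf that split is trivial, so the
    # edge subtending {focal, sister} (the parent node) is inspected.
    support_node = focal_clade if not focal_clade.is_leaf() else focal_clade.parent_node
    cls.inspected_branch_support = getattr(support_node, "support", None)
    cls.support_tier = support_tier(cls.inspected_branch_support, config)

    cls.direction = _infer_direction(gtree, focal_clade, status, sister, config)
    cls.only_archaea_rescue = cls.only_archaea and cls.direction == UNKNOWN
    if cls.only_archaea_rescue:
        notes.append(
            "focal and companion genera are the only archaea on the tree; "
            "bacterial origin likely despite unknown direction"
        )

    phyla = {r.phylum for r in neighbor}
    cls.donor_phylum = phyla.pop() if len(phyla) == 1 else UNDETERMINED
    if not cls.donor_phylum:
        cls.donor_phylum = UNDETERMINED
    return cls


def _other_side(gtree, node) -> list[TaxonRecord]:
    """Leaves of node's parent that are not under node (its sister group)."""
    parent = node.parent_node
    if parent is None:
        return []
    own = {lf.taxon.label for lf in node.leaf_iter()}
    return [r for r in _leaf_records(gtree, parent) if r.leaf_id not in own]


def _only_focal_and_companion_archaea(gtree, config) -> bool:
    for record in (gtree.annotations[lid] for lid in gtree.leaf_ids):
        if record.domain != "Archaea":
            continue
        if record.species == config.focal_species:
            continue
        if record.genus == config.companion_genus:
            continue
        return False
    return True


def _infer_direction(gtree, focal_clade, status, sister, config) -> str:
    if status in (LGT_BACTERIAL, LGT_NESTED):
        if _nested_in_pure_domain(
            gtree, focal_clade, "Bacteria",
            min_groups=config.min_bacterial_phyla,
            group_key=lambda r: r.phylum,
            max_levels=config.max_nesting_levels,
        ):
            return B_TO_A
    if status == LGT_BACTERIAL and len(sister) <= config.max_export_sister_leaves:
        if _archaeal_context(gtree, focal_clade, config):
            return A_TO_B
    if status == LGT_EUKARYOTE:
        if _nested_in_pure_domain(
            gtree, focal_clade, "Eukaryota",
            min_groups=1,
            group_key=lambda r: r.species,
            max_levels=config.max_nesting_levels,
        ):
            return E_TO_A
    return UNKNOWN


def _nested_in_pure_domain(gtree, focal_clade, domain, min_groups, group_key,
                           max_levels=None) -> bool:
    """True when the focal clade is *unambiguously* nested in ``domain``.

    Ascends through proper ancestors, excluding the root: the two sides of
    the root are an artifact of rooting an unrooted gene tree, so a clade
    whose enclosure sits directly opposite the rest of the tree cannot be
    oriented. Nesting requires at least two successive enclosure levels
    whose added members are all of ``domain``, jointly spanning
    ``min_groups`` distinct groups (phyla for bacteria). Ascent stops at
    the first level contaminated by another domain.
    """
    own = {lf.taxon.label for lf in focal_clade.leaf_iter()}
    anc = focal_clade.parent_node
    levels = 0
    groups: set = set()
    while anc is not None and anc.parent_node is not None:
        rest = [r for r in _leaf_records(gtree, anc) if r.leaf_id not in own]
        if rest:
            if any(r.domain != domain for r in rest):
                return False
            levels += 1
            groups.update(group_key(r) for r in rest)
            if levels >= 2 and len(groups) >= min_groups:
                return True
        if max_levels is not None and levels >= max_levels:
            return False
        anc = anc.parent_node
    return False


def _archaeal_context(gtree, focal_clade, config) -> bool:
    """True when the focal leaf + its small bacterial sister sit inside an
    otherwise archaeal clade spanning enough distinct non-focal genera.

    The root's opposite side is excluded for the same rooting-ambiguity
    reason as in bacterial nesting.
    """
    pair = focal_clade.parent_node  # focal + bacterial insert
    if pair is None:
        return False
    own = {lf.taxon.label for lf in pair.leaf_iter()}
    focal_genus = config.focal_species.split()[0]
    anc = pair.parent_node
    while anc is not None and anc.parent_node is not None:
        rest = [r for r in _leaf_records(gtree, anc) if r.leaf_id not in own]
        if rest:
            if any(r.domain != "Archaea" for r in rest):
                return False
            genera = {r.genus for r in rest} - {focal_genus}
            if len(genera) >= config.min_archaeal_context_genera:
                return True
        anc = anc.parent_node
    return False


# ---------------------------------------------------------------------------
# tabular output

TSV_COLUMNS = [
    "gene_id", "status", "companion_present", "direction",
    "only_archaea_rescue", "support", "tier", "donor_phylum",
]


def classification_row(cls: TreeClassification) -> dict:
    return {
        "gene_id": cls.gene_id,
        "status": cls.status,
        "companion_present": cls.companion_present,
        "direction": cls.direction,
        "only_archaea_rescue": int(cls.only_archaea_rescue),
        "support": "" if cls.inspected_branch_support is None
        else cls.inspected_branch_support,
        "tier": cls.support_tier,
        "donor_phylum": cls.donor_phylum,
    }


def write_classifications(classifications, path) -> None:
    import pandas as pd

    pd.DataFrame(
        [classification_row(c) for c in classifications], columns=TSV_COLUMNS
    ).to_csv(path, sep="\t", index=False)


def read_classifications(path) -> list[TreeClassification]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"support": "Int64"})
    out = []
    for row in df.itertuples():
        support = None if pd.isna(row.support) else int(row.support)
        out.append(
            TreeClassification(
                gene_id=str(row.gene_id),
                status=row.status,
                companion_present=row.companion_present,
                direction=row.direction,
                only_archaea_rescue=bool(row.only_archaea_rescue),
                inspected_branch_support=support,
                support_tier=row.tier,
                donor_phylum=row.donor_phylum,
            )
        )
    return out
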
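"""Merge NJ- and ML-based per-gene LGT verdicts and aggregate the screen.

A gene is a *confirmed* LGT candidate only when both tree-inference
methods recover an LGT topology. Direction is taken from whichever method
resolves it; if both resolve it they must agree, otherwise the record is
conflict-flagged and excluded from origin totals. A gene whose direction
neither method resolves is still called bacterial-origin when either
method observed that the focal and companion genera were the only archaea
on the tree (the only-archaea rescue).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, asdict

from .lgt_classify import (
    A_TO_B,
    B_TO_A,
    E_TO_A,
    NOT_APPLICABLE,
    TIER_HIGH,
    TIER_MODERATE,
    TreeClassification,
    UNKNOWN,
)

# final_status values
LGT_CONFIRMED = "LGT_confirmed"
LGT_NJ_ONLY = "LGT_nj_only"
NON_LGT_FINAL = "non_LGT"
UNRESOLVED_TOO_FEW = "unresolved_too_few_taxa"

# sentinel for genes whose alignment had too few taxa for ML re-analysis
TOO_FEW_TAXA = "too_few_taxa"

# origin calls
ORIGIN_BACTERIAL = "bacterial"
ORIGIN_EUKARYOTIC = "eukaryotic"
ORIGIN_ARCHAEA_EXPORT = "archaea_export"
ORIGIN_UNDETERMINED = "undetermined"


@dataclass
class ConsensusRecord:
    gene_id: str
    nj: TreeClassification
    ml: TreeClassification | str | None  # classification, TOO_FEW_TAXA, or not run
    final_status: str
    final_direction: str
    origin_call: str
    direction_conflict: bool = False


def merge(nj: TreeClassification, ml: TreeClassification | str | None) -> ConsensusRecord:
    """Combine the NJ and ML verdicts for one gene.

    ``ml`` may be a :class:`TreeClassification`, the :data:`TOO_FEW_TAXA`
    sentinel (alignment below the ML method's minimum taxon count), or
    ``None`` when ML was not run for this gene.
    """
    if isinstance(ml, TreeClassification) and ml.gene_id != nj.gene_id:
        raise ValueError(f"gene_id mismatch: {nj.gene_id!r} vs {ml.gene_id!r}")
    if isinstance(ml, str) and ml != TOO_FEW_TAXA:
        raise ValueError(f"unknown ML sentinel {ml!r}")

    if not nj.is_lgt:
        final_status = NON_LGT_FINAL
    elif ml == TOO_FEW_TAXA:
        final_status = UNRESOLVED_TOO_FEW
    elif ml is None:
        final_status = LGT_NJ_ONLY
    elif ml.is_lgt:
        final_status = LGT_CONFIRMED
    else:
        final_status = NON_LGT_FINAL

    resolved = [
        d
        for d in (
            nj.direction,
            ml.direction if isinstance(ml, TreeClassification) else NOT_APPLICABLE,
        )
        if d not in (UNKNOWN, NOT_APPLICABLE)
    ]
    conflict = len(set(resolved)) > 1
    if conflict:
        final_direction = UNKNOWN
    elif resolved:
        final_direction = resolved[0]
    elif final_status == NON_LGT_FINAL:
        final_direction = NOT_APPLICABLE
    else:
        final_direction = UNKNOWN

    rescue = nj.only_archaea_rescue or (
        isinstance(ml, TreeClassification) and ml.only_archaea_rescue
    )
    origin = ORIGIN_UNDETERMINED
    if final_status == LGT_CONFIRMED and not conflict:
        if final_direction == B_TO_A or rescue:
            origin = ORIGIN_BACTERIAL
        elif final_direction == E_TO_A:
            origin = ORIGIN_EUKARYOTIC
        elif final_direction == A_TO_B:
            origin = ORIGIN_ARCHAEA_EXPORT

    return ConsensusRecord(
        gene_id=nj.gene_id,
        nj=nj,
        ml=ml,
        final_status=final_status,
        final_direction=final_direction,
        origin_call=origin,
        direction_conflict=conflict,
    )


@dataclass
class SummaryReport:
    """Aggregated screen counts; every histogram is a plain dict."""

    n_genes: int = 0
    n_trees: int = 0
    n_proteome: int = 0
    status_counts: dict = field(default_factory=dict)
    companion_counts: dict = field(default_factory=dict)
    nj_direction_hist: dict = field(default_factory=dict)
    ml_direction_hist: dict = field(default_factory=dict)
    nj_donor_hist: dict = field(default_factory=dict)
    ml_donor_hist: dict = field(default_factory=dict)
    nj_tier_by_direction: dict = field(default_factory=dict)
    ml_tier_by_direction: dict = field(default_factory=dict)
    nj_rescue_by_tier: dict = field(default_factory=dict)
    final_status_counts: dict = field(default_factory=dict)
    candidate_total: int = 0
    confirmed_total: int = 0
    too_few_taxa: int = 0
    conflicts: int = 0
    agreement_pct: float = 0.0
    pct_of_trees: float = 0.0
    pct_of_proteome: float = 0.0
    bacterial_origin_total: int = 0
    eukaryotic_total: int = 0
    archaea_export_total: int = 0
    interdomain_total: int = 0
    nj_events_total: int = 0
    ml_good_support: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SummaryReport":
        return cls(**data)


def summarize(
    records: list[ConsensusRecord],
    n_trees: int | None = None,
    n_proteome: int | None = None,
) -> SummaryReport:
    """Aggregate per-gene consensus records into the screen's headline counts.

    ``n_trees`` (number of gene trees built) and ``n_proteome`` (annotated
    proteins in the genome) are the denominators of the candidate
    percentages; they default to the number of records.
    """
    gene_ids = [r.gene_id for r in records]
    dupes = [g for g, c in Counter(gene_ids).items() if c > 1]
    if dupes:
        raise ValueError(f"duplicate gene_id in records: {sorted(dupes)[:5]}")

    n = len(records)
    n_trees = n_trees if n_trees is not None else n
    n_proteome = n_proteome if n_proteome is not None else n
    rep = SummaryReport(n_genes=n, n_trees=n_trees, n_proteome=n_proteome)
    if n == 0:
        return rep

    candidates = [r for r in records if r.nj.is_lgt]
    rep.candidate_total = len(candidates)
    rep.status_counts = dict(Counter(r.nj.status for r in records))
    rep.companion_counts = dict(
        Counter(r.nj.companion_present for r in candidates)
    )
    rep.final_status_counts = dict(Counter(r.final_status for r in records))

    rep.nj_direction_hist = dict(Counter(r.nj.direction for r in candidates))
    ml_lgt = [
        r for r in records
        if isinstance(r.ml, TreeClassification) and r.ml.is_lgt
    ]
    rep.ml_direction_hist = dict(Counter(r.ml.direction for r in ml_lgt))

    rep.nj_donor_hist = dict(Counter(r.nj.donor_phylum for r in candidates))
    rep.ml_donor_hist = dict(Counter(r.ml.donor_phylum for r in ml_lgt))

    def tier_cross(classes):
        cross: dict[str, dict[str, int]] = {}
        for c in classes:
            cross.setdefault(c.direction, Counter())[c.support_tier] += 1
        return {d: dict(v) for d, v in cross.items()}

    rep.nj_tier_by_direction = tier_cross([r.nj for r in candidates])
    rep.ml_tier_by_direction = tier_cross([r.ml for r in ml_lgt])
    rep.nj_rescue_by_tier = dict(
        Counter(
            r.nj.support_tier for r in candidates if r.nj.only_archaea_rescue
        )
    )

    rep.confirmed_total = sum(1 for r in records if r.final_status == LGT_CONFIRMED)
    rep.too_few_taxa = sum(1 for r in records if r.final_status == UNRESOLVED_TOO_FEW)
    rep.conflicts = sum(1 for r in records if r.direction_conflict)
    if rep.candidate_total:
        rep.agreement_pct = round(100.0 * rep.confirmed_total / rep.candidate_total, 2)
    rep.pct_of_trees = round(100.0 * rep.candidate_total / n_trees, 2)
    rep.pct_of_proteome = round(100.0 * rep.candidate_total / n_proteome, 2)

    origins = Counter(r.origin_call for r in records if r.final_status == LGT_CONFIRMED)
    rep.bacterial_origin_total = origins.get(ORIGIN_BACTERIAL, 0)
    rep.eukaryotic_total = origins.get(ORIGIN_EUKARYOTIC, 0)
    rep.archaea_export_total = origins.get(ORIGIN_ARCHAEA_EXPORT, 0)
    rep.interdomain_total = (
        rep.bacterial_origin_total + rep.eukaryotic_total + rep.archaea_export_total
    )

    # NJ event total, tier-aggregation style: every bacteria->archaea call
    # regardless of support, plus the direction-unknown only-archaea rescues
    nj_b_to_a = sum(1 for r in candidates if r.nj.direction == B_TO_A)
    nj_rescues = sum(1 for r in candidates if r.nj.only_archaea_rescue)
    rep.nj_events_total = nj_b_to_a + nj_rescues

    # ML trees whose direction is resolved (or rescued) with decent support
    rep.ml_good_support = sum(
        1
        for r in ml_lgt
        if (r.ml.direction not in (UNKNOWN, NOT_APPLICABLE) or r.ml.only_archaea_rescue)
        and r.ml.support_tier in (TIER_HIGH, TIER_MODERATE)
    )
    return rep
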
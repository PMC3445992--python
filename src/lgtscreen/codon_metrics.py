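"""Codon adaptation index (CAI) and effective number of codons (ENC).

Both statistics probe the amelioration of laterally acquired genes: a
recent transfer keeps donor-like codon usage (low CAI against the host's
highly expressed reference set, often high ENC), while ancient transfers
have drifted toward the host's codon preferences and are indistinguishable
from native genes.

CAI is the geometric mean over a gene's codons of each codon's relative
adaptiveness w (codon count in the reference set divided by the count of
its most-used synonym), excluding Met, Trp, and stops, whose codon choice
is not free. ENC estimates how many distinct codons a gene effectively
uses (20 = one per amino acid, 61 = uniform synonymous usage) from the
synonymous homozygosity of each degeneracy class of the genetic code.

The bacterial/archaeal genetic code (translation table 11) is used: nine
two-fold, one three-fold, five four-fold, and three six-fold degenerate
amino acids.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[11]

#: amino acid -> tuple of synonymous codons (DNA alphabet)
SYNONYMS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _TABLE.forward_table.items():
    SYNONYMS.setdefault(_aa, ())
    SYNONYMS[_aa] += (_codon,)

STOP_CODONS = frozenset(_TABLE.stop_codons)
CODON_TO_AA = dict(_TABLE.forward_table)

#: amino acids excluded from CAI (single effective codon choice)
CAI_EXCLUDED_AA = frozenset(
    aa for aa, codons in SYNONYMS.items() if len(codons) == 1
)  # Met, Trp under table 11

#: degeneracy class -> (number of amino acids, ENC weight)
DEGENERACY_CLASSES = {2: 9, 3: 1, 4: 5, 6: 3}


class CodonSequenceError(ValueError):
    pass


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame coding sequence over {A, C, G, T, N}.

    A terminal stop codon is trimmed on construction. Internal stops are
    an error in strict mode, logged otherwise. Codons containing N are
    skipped in all calculations and counted in ``n_ambiguous``.
    """

    gene_id: str
    nucleotides: str
    n_ambiguous: int = 0

    @classmethod
    def from_string(cls, gene_id: str, seq: str, strict: bool = True) -> "CodingSequence":
        seq = seq.upper().replace("U", "T")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise CodonSequenceError(f"{gene_id}: invalid characters {sorted(bad)}")
        if len(seq) % 3 != 0:
            raise CodonSequenceError(
                f"{gene_id}: length {len(seq)} not divisible by 3"
            )
        if len(seq) >= 3 and seq[-3:] in STOP_CODONS:
            seq = seq[:-3]
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        internal_stops = [c for c in codons if c in STOP_CODONS]
        if internal_stops:
            msg = f"{gene_id}: {len(internal_stops)} internal stop codon(s)"
            if strict:
                raise CodonSequenceError(msg)
            logger.warning(msg)
        n_ambig = sum(1 for c in codons if "N" in c)
        return cls(gene_id=gene_id, nucleotides=seq, n_ambiguous=n_ambig)

    def codons(self) -> list[str]:
        """Unambiguous, non-stop codons in frame 0."""
        seq = self.nucleotides
        return [
            seq[i : i + 3]
            for i in range(0, len(seq), 3)
            if "N" not in seq[i : i + 3] and seq[i : i + 3] not in STOP_CODONS
        ]


def read_cds_fasta(path, strict: bool = True) -> list[CodingSequence]:
    return [
        CodingSequence.from_string(rec.id, str(rec.seq), strict=strict)
        for rec in SeqIO.parse(path, "fasta")
    ]


# ---------------------------------------------------------------------------
# CAI


@dataclass
class ReferenceUsage:
    """Relative adaptiveness w per codon, from a highly expressed gene set.

    Zero reference counts are replaced by a 0.5 pseudo-count before
    normalization; an amino acid entirely absent from the reference gets
    w = 1 for all its codons (neutral in CAI) and is logged.
    """

    counts: dict[str, float]
    w: dict[str, float]

    @classmethod
    def from_counts(cls, counts: Mapping[str, float]) -> "ReferenceUsage":
        counts = {c.upper().replace("U", "T"): v for c, v in counts.items()}
        w: dict[str, float] = {}
        for aa, codons in SYNONYMS.items():
            family = {c: float(counts.get(c, 0.0)) for c in codons}
            if all(v == 0 for v in family.values()):
                logger.warning(
                    "reference set lacks amino acid %s; its codons get w=1", aa
                )
                for c in codons:
                    w[c] = 1.0
                continue
            adjusted = {c: (v if v > 0 else 0.5) for c, v in family.items()}
            top = max(adjusted.values())
            for c in codons:
                w[c] = adjusted[c] / top
        return cls(counts=dict(counts), w=w)

    @classmethod
    def from_sequences(cls, seqs: Iterable[CodingSequence]) -> "ReferenceUsage":
        counts: dict[str, float] = {}
        for s in seqs:
            for c in s.codons():
                counts[c] = counts.get(c, 0) + 1
        return cls.from_counts(counts)


def relative_adaptiveness(counts: Mapping[str, float]) -> ReferenceUsage:
    """Functional alias for :meth:`ReferenceUsage.from_counts`."""
    return ReferenceUsage.from_counts(counts)


def cai(seq: CodingSequence, ref: ReferenceUsage) -> float:
    """Geometric mean of w over the gene's codons (Met/Trp/stops excluded)."""
    logs = [
        math.log(ref.w[c])
        for c in seq.codons()
        if CODON_TO_AA[c] not in CAI_EXCLUDED_AA
    ]
    if not logs:
        raise CodonSequenceError(f"{seq.gene_id}: no informative codons for CAI")
    return math.exp(sum(logs) / len(logs))


# ---------------------------------------------------------------------------
# ENC


def enc(seq: CodingSequence) -> float:
    """Wright's effective number of codons, clamped to [20, 61].

    Per amino acid observed n >= 2 times, the synonymous homozygosity is
    F = (n * sum(p_i^2) - 1) / (n - 1); class means over amino acids of
    equal degeneracy give ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6. A missing
    three-fold class (no Ile observed) is estimated as
    1 / (2/F2 - 1/F4), falling back to (F2 + F4)/2 when that expression
    is non-positive; a missing six-fold class is estimated by the
    four-fold mean. Missing two- or four-fold classes are an error
    (sequence too short to estimate ENC).
    """
    counts: dict[str, dict[str, int]] = {}
    for codon in seq.codons():
        aa = CODON_TO_AA[codon]
        counts.setdefault(aa, {})
        counts[aa][codon] = counts[aa].get(codon, 0) + 1

    class_f: dict[int, list[float]] = {k: [] for k in DEGENERACY_CLASSES}
    for aa, codon_counts in counts.items():
        k = len(SYNONYMS[aa])
        if k not in DEGENERACY_CLASSES:
            continue  # Met, Trp: no synonymous choice
        n = sum(codon_counts.values())
        if n < 2:
            continue
        s = sum((c / n) ** 2 for c in codon_counts.values())
        f = (n * s - 1) / (n - 1)
        if f <= 0:
            logger.debug("%s: F<=0 for %s; excluded from class mean", seq.gene_id, aa)
            continue
        class_f[k].append(f)

    fbar: dict[int, float] = {
        k: float(np.mean(v)) for k, v in class_f.items() if v
    }
    if 2 not in fbar or 4 not in fbar:
        raise CodonSequenceError(
            f"{seq.gene_id}: too short to estimate ENC (missing degeneracy class)"
        )
    if 3 not in fbar:
        denom = 2.0 / fbar[2] - 1.0 / fbar[4]
        if denom > 0:
            fbar[3] = 1.0 / denom
        else:
            fbar[3] = (fbar[2] + fbar[4]) / 2.0
        logger.debug("%s: three-fold class missing; interpolated", seq.gene_id)
    if 6 not in fbar:
        fbar[6] = fbar[4]
        logger.debug("%s: six-fold class missing; used four-fold mean", seq.gene_id)

    value = 2.0 + 9.0 / fbar[2] + 1.0 / fbar[3] + 5.0 / fbar[4] + 3.0 / fbar[6]
    return float(min(61.0, max(20.0, value)))


# ---------------------------------------------------------------------------
# background statistics and outlier flags


@dataclass
class CodonMetrics:
    gene_id: str
    cai: float
    enc: float
    cai_z: float = float("nan")
    enc_z: float = float("nan")
    flags: frozenset = frozenset()


@dataclass
class BackgroundStats:
    n_background: int
    cai_mean: float
    cai_sd: float
    enc_mean: float
    enc_sd: float

    @property
    def enc_low_threshold(self) -> float:
        return self.enc_mean - 2 * self.enc_sd

    @property
    def enc_high_threshold(self) -> float:
        return self.enc_mean + 2 * self.enc_sd

    @property
    def cai_low_threshold(self) -> float:
        return self.cai_mean - 2 * self.cai_sd

    @property
    def cai_high_threshold(self) -> float:
        return self.cai_mean + 2 * self.cai_sd


def compute_metrics(
    seqs: Iterable[CodingSequence], ref: ReferenceUsage
) -> list[CodonMetrics]:
    return [
        CodonMetrics(gene_id=s.gene_id, cai=cai(s, ref), enc=enc(s)) for s in seqs
    ]


def background_and_flags(
    metrics: Sequence[CodonMetrics],
    background: Sequence[CodonMetrics],
    exclusions: Iterable[str] = (),
) -> tuple[list[CodonMetrics], BackgroundStats]:
    """Z-scores and +/-2 SD outlier flags against a genomic background.

    The background is the genome-wide metric list minus the CAI reference
    genes (whose usage defines w and would bias the CAI mean upward).
    Flags mark genes strictly beyond two standard deviations. Zero
    variance suppresses flags with a warning.
    """
    excluded = set(exclusions)
    bg = [m for m in background if m.gene_id not in excluded]
    if len(bg) < 10:
        raise ValueError(
            f"background has {len(bg)} genes after exclusions; need >= 10"
        )
    cai_vals = np.array([m.cai for m in bg])
    enc_vals = np.array([m.enc for m in bg])

    def _sd(values):  # rounding dust on a constant background is zero
        sd = float(values.std(ddof=1))
        return sd if sd > 1e-9 * max(1.0, abs(float(values.mean()))) else 0.0

    stats = BackgroundStats(
        n_background=len(bg),
        cai_mean=float(cai_vals.mean()),
        cai_sd=_sd(cai_vals),
        enc_mean=float(enc_vals.mean()),
        enc_sd=_sd(enc_vals),
    )

    out = []
    for m in metrics:
        flags = set()
        if stats.cai_sd > 0:
            cai_z = (m.cai - stats.cai_mean) / stats.cai_sd
            if cai_z < -2:
                flags.add("low_CAI")
            elif cai_z > 2:
                flags.add("high_CAI")
        else:
            cai_z = 0.0
        if stats.enc_sd > 0:
            enc_z = (m.enc - stats.enc_mean) / stats.enc_sd
            if enc_z < -2:
                flags.add("low_ENC")
            elif enc_z > 2:
                flags.add("high_ENC")
        else:
            enc_z = 0.0
        out.append(replace(m, cai_z=cai_z, enc_z=enc_z, flags=frozenset(flags)))
    if stats.cai_sd == 0 or stats.enc_sd == 0:
        logger.warning("zero background variance; outlier flags suppressed")
    return out, stats


def mean_metrics(metrics: Sequence[CodonMetrics]) -> dict[str, float]:
    """Subgroup means (e.g., LGT candidates vs the genomic average)."""
    if not metrics:
        return {"n": 0, "cai_mean": float("nan"), "enc_mean": float("nan")}
    return {
        "n": len(metrics),
        "cai_mean": float(np.mean([m.cai for m in metrics])),
        "enc_mean": float(np.mean([m.enc for m in metrics])),
    }


def write_metrics(metrics: Sequence[CodonMetrics], path) -> None:
    import pandas as pd

    rows = [
        {
            "gene_id": m.gene_id,
            "cai": m.cai,
            "enc": m.enc,
            "cai_z": m.cai_z,
            "enc_z": m.enc_z,
            "flags": ",".join(sorted(m.flags)),
        }
        for m in metrics
    ]
    pd.DataFrame(rows, columns=["gene_id", "cai", "enc", "cai_z", "enc_z", "flags"]).to_csv(
        path, sep="\t", index=False
    )
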
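"""Domain-architecture (DA) classification from domain-hit tables.

A protein's DA is the linear N-terminal-to-C-terminal composition of its
identified domains, with an optional trailing ``Ct`` label for an
unidentified C-terminal extension binned by length, and a kingdom suffix
(``-E`` eukarya, ``-A`` archaea, none for prokarya).

Sequences are admitted only when a catalytic-domain hit covers at least 80%
of the domain model's consensus length (the family's retrieval rule);
sequences whose best catalytic hit falls below the threshold are discarded.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger("xynscreen.architecture")

CATALYTIC_LABEL = "GH11"
KINGDOMS = ("prokarya", "eukarya", "archaea")
KINGDOM_SUFFIX = {"prokarya": "", "eukarya": "-E", "archaea": "-A"}

#: C-terminal tail bins: half-open [lo, hi), except the last which is
#: closed [400, 500].  Tails shorter than 50 aa are not labelled.
DEFAULT_CT_BINS: tuple[tuple[str, int, int], ...] = (
    ("Ct1", 50, 150),
    ("Ct2", 150, 200),
    ("Ct3", 200, 300),
    ("Ct4", 300, 400),
    ("Ct5", 400, 500),
)

HIT_COLUMNS = [
    "seq_id", "domain", "model_len",
    "ali_from", "ali_to", "hmm_from", "hmm_to",
    "score", "evalue",
]

_STANDARD_AA = set("ARNDCQEGHILKMFPSTWYV")


class ClassificationError(ValueError):
    pass


@dataclass
class SequenceRecord:
    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues) - _STANDARD_AA
        if bad:
            raise ValueError(f"{self.id}: nonstandard residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class DomainHit:
    """One domain match with 1-based inclusive coordinates on both the
    protein (``seq_start``..``seq_end``) and the domain model."""

    seq_id: str
    domain_name: str
    model_length: int
    seq_start: int
    seq_end: int
    model_start: int
    model_end: int
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if not (1 <= self.seq_start <= self.seq_end):
            raise ValueError(f"{self.seq_id}: bad sequence coordinates")
        if not (1 <= self.model_start <= self.model_end <= self.model_length):
            raise ValueError(f"{self.seq_id}: bad model coordinates")
        if self.evalue < 0:
            raise ValueError(f"{self.seq_id}: negative e-value")


@dataclass
class DomainArchitecture:
    seq_id: str
    ordered_labels: list[str]
    kingdom: str
    ct_label: str | None = None

    @property
    def da_string(self) -> str:
        labels = self.ordered_labels + ([self.ct_label] if self.ct_label else [])
        return "+".join(labels) + KINGDOM_SUFFIX[self.kingdom]

    @property
    def is_bare(self) -> bool:
        """True when the DA is the catalytic domain alone (no CBM, no tail)."""
        return self.ordered_labels == [CATALYTIC_LABEL] and self.ct_label is None

    @property
    def has_cbm(self) -> bool:
        return any(lbl.startswith("CBM") for lbl in self.ordered_labels)

    @property
    def has_ct(self) -> bool:
        return self.ct_label is not None


# ---------------------------------------------------------------------------
# File readers (formats shared with the synthetic generator)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read protein FASTA; sequences with nonstandard letters are skipped
    with a warning rather than aborting the batch."""
    from Bio import SeqIO

    out: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            out.append(SequenceRecord(rec.id, rec.description, str(rec.seq).upper()))
        except ValueError as exc:
            logger.warning("skipping %s: %s", rec.id, exc)
    return out


def read_hits(path: str | Path) -> list[DomainHit]:
    """Read the tab-separated domain-hit table (domtblout-like)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    return [
        DomainHit(
            seq_id=str(r.seq_id), domain_name=str(r.domain),
            model_length=int(r.model_len),
            seq_start=int(r.ali_from), seq_end=int(r.ali_to),
            model_start=int(r.hmm_from), model_end=int(r.hmm_to),
            score=float(r.score), evalue=float(r.evalue),
        )
        for r in df.itertuples()
    ]


def read_taxonomy(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read ``seq_id <tab> genus <tab> kingdom`` into a mapping."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, tuple[str, str]] = {}
    for r in df.itertuples():
        kingdom = str(r.kingdom)
        if kingdom not in KINGDOMS:
            raise ValueError(f"unknown kingdom {kingdom!r} for {r.seq_id}")
        out[str(r.seq_id)] = (str(r.genus), kingdom)
    return out


# ---------------------------------------------------------------------------
# Classification steps
# ---------------------------------------------------------------------------

def coverage(hit: DomainHit) -> float:
    """Fraction of the domain model spanned by the hit, in (0, 1]."""
    if hit.model_length <= 0:
        raise ValueError("model_length must be positive")
    return (hit.model_end - hit.model_start + 1) / hit.model_length


def filter_by_coverage(
    hits: list[DomainHit],
    catalytic_label: str = CATALYTIC_LABEL,
    threshold: float = 0.80,
) -> tuple[set[str], list[DomainHit]]:
    """Keep sequences with at least one catalytic hit covering >= threshold
    of the model (the boundary value itself is retained; only strictly lower
    coverage is discarded).

    Returns ``(retained_ids, retained_hits)``.  Non-catalytic hits of
    retained sequences pass through untouched; sub-threshold catalytic hits
    are dropped everywhere.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    retained: set[str] = {
        h.seq_id
        for h in hits
        if h.domain_name == catalytic_label and coverage(h) >= threshold
    }
    kept = [
        h
        for h in hits
        if h.seq_id in retained
        and (h.domain_name != catalytic_label or coverage(h) >= threshold)
    ]
    return retained, kept


def resolve_overlaps(hits: list[DomainHit], max_overlap: int = 10) -> list[DomainHit]:
    """Greedy overlap resolution on one sequence: take hits by descending
    score, keep a hit only if it overlaps every already-kept hit by at most
    ``max_overlap`` residues.  Output is sorted by sequence start."""
    kept: list[DomainHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.seq_start, h.domain_name)):
        ok = True
        for other in kept:
            ov = min(h.seq_end, other.seq_end) - max(h.seq_start, other.seq_start) + 1
            if ov > max_overlap:
                ok = False
                break
        if ok:
            kept.append(h)
    return sorted(kept, key=lambda h: (h.seq_start, h.seq_end, h.domain_name))


def annotate_ct_tail(
    seq_len: int,
    hits: list[DomainHit],
    bins: tuple[tuple[str, int, int], ...] = DEFAULT_CT_BINS,
) -> str | None:
    """Label the unannotated C-terminal tail by length, or None if < 50 aa.

    Tails longer than the last bin keep the last bin's label with a warning
    (the binning was defined only up to 500 aa).
    """
    if not hits:
        raise ValueError("cannot measure a tail without any domain hit")
    if seq_len < max(h.seq_end for h in hits):
        raise ValueError("sequence shorter than its last domain hit")
    tail = seq_len - max(h.seq_end for h in hits)
    if tail < bins[0][1]:
        return None
    last_label, _, last_hi = bins[-1]
    if tail > last_hi:
        logger.warning("C-terminal tail of %d aa exceeds %d; labelled %s",
                       tail, last_hi, last_label)
        return last_label
    for label, lo, hi in bins[:-1]:
        if lo <= tail < hi:
            return label
    return last_label  # closed last bin [lo, hi]


def classify_architecture(
    seq: SequenceRecord,
    hits: list[DomainHit],
    kingdom: str,
    bins: tuple[tuple[str, int, int], ...] = DEFAULT_CT_BINS,
    catalytic_label: str = CATALYTIC_LABEL,
) -> DomainArchitecture:
    """Build the DA of one retained sequence from its kept hits."""
    if kingdom not in KINGDOMS:
        raise ValueError(f"unknown kingdom {kingdom!r}")
    kept = resolve_overlaps([h for h in hits if h.seq_id == seq.id])
    if not kept:
        raise ClassificationError(f"{seq.id}: no kept hits to classify")
    n_cat = sum(1 for h in kept if h.domain_name == catalytic_label)
    if n_cat > 1:
        logger.info("%s: %d catalytic hits retained in one DA", seq.id, n_cat)
    ct = annotate_ct_tail(len(seq), kept, bins)
    return DomainArchitecture(
        seq_id=seq.id,
        ordered_labels=[h.domain_name for h in kept],
        kingdom=kingdom,
        ct_label=ct,
    )


def check_nterminal(hit: DomainHit, tolerance: int = 50) -> bool:
    """True when the hit starts within ``tolerance`` residues of the
    N-terminus (slack allows untrimmed signal peptides)."""
    return hit.seq_start <= tolerance


def classify_all(
    seqs: list[SequenceRecord],
    hits: list[DomainHit],
    taxonomy: dict[str, tuple[str, str]],
    threshold: float = 0.80,
    catalytic_label: str = CATALYTIC_LABEL,
    bins: tuple[tuple[str, int, int], ...] = DEFAULT_CT_BINS,
) -> tuple[list[DomainArchitecture], set[str]]:
    """Filter + classify a batch.  Returns (architectures, discarded ids)."""
    retained, kept_hits = filter_by_coverage(hits, catalytic_label, threshold)
    by_seq: dict[str, list[DomainHit]] = defaultdict(list)
    for h in kept_hits:
        by_seq[h.seq_id].append(h)
    das: list[DomainArchitecture] = []
    for seq in seqs:
        if seq.id not in retained:
            continue
        kingdom = taxonomy[seq.id][1]
        das.append(classify_architecture(seq, by_seq[seq.id], kingdom,
                                         bins, catalytic_label))
    discarded = {s.id for s in seqs} - retained
    return das, discarded


def tabulate_architectures(das: list[DomainArchitecture]) -> pd.DataFrame:
    """Frequency table of DA strings per kingdom.

    Columns: da_string, kingdom, count, fraction (within kingdom), sorted by
    kingdom then descending count.
    """
    if not das:
        return pd.DataFrame(columns=["da_string", "kingdom", "count", "fraction"])
    df = pd.DataFrame({"da_string": [d.da_string for d in das],
                       "kingdom": [d.kingdom for d in das]})
    tab = (df.groupby(["kingdom", "da_string"], sort=True)
             .size().rename("count").reset_index())
    tab["fraction"] = tab["count"] / tab.groupby("kingdom")["count"].transform("sum")
    tab = tab.sort_values(["kingdom", "count", "da_string"],
                          ascending=[True, False, True]).reset_index(drop=True)
    return tab[["da_string", "kingdom", "count", "fraction"]]
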
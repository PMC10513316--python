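"""Barcoded amplicon read counting and mutant-allele-ratio estimation.

Each sample is amplified with a three-part forward primer
(15-mer pad + 24-mer barcode + annealing part); all samples are pooled
and sequenced together.  A read is attributed to a sample when exactly
one panel barcode occurs in it, and to an allele when exactly one of two
k-mer allele signatures (the SNV-spanning k-mer with the wild-type or
the mutant base) co-occurs with the barcode.  The default is exact
substring co-occurrence, equivalent to counting regular-expression hits
over the raw FASTQ; an edit-distance-tolerant mode (``max_mismatch > 0``,
via edlib) is available for noisier reads but off by default.

The per-barcode mutation ratio is 100 * n_mu / (n_wt + n_mu), rounded
half-up to one decimal, and is only trusted at sufficient depth
(>= 1000 informative reads by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, List, Literal, Optional, Sequence, Tuple, Union

import edlib
from Bio.Seq import reverse_complement

Allele = Literal["wt", "mu", "ambiguous", "unassigned"]


@dataclass(frozen=True)
class BarcodeSpec:
    """One barcoded forward primer: pad + barcode + annealing part."""

    barcode_id: str
    pad_seq: str
    barcode_seq: str
    annealing_seq: str
    five_prime_phosphate: bool = False

    def __post_init__(self) -> None:
        for name in ("pad_seq", "barcode_seq", "annealing_seq"):
            object.__setattr__(self, name, getattr(self, name).upper())
        if not self.barcode_seq:
            raise ValueError("barcode_seq must be non-empty")

    @property
    def assembled(self) -> str:
        """Full primer sequence 5'->3'."""
        return self.pad_seq + self.barcode_seq + self.annealing_seq


@dataclass(frozen=True)
class AlleleSignature:
    """SNV-spanning k-mers distinguishing the two alleles.

    The two signatures have equal length and differ at exactly one
    position (the substitution site).
    """

    wt_signature: str
    mu_signature: str

    def __post_init__(self) -> None:
        wt = self.wt_signature.upper()
        mu = self.mu_signature.upper()
        object.__setattr__(self, "wt_signature", wt)
        object.__setattr__(self, "mu_signature", mu)
        if len(wt) != len(mu):
            raise ValueError("signatures must have equal length")
        diffs = sum(a != b for a, b in zip(wt, mu))
        if diffs != 1:
            raise ValueError(
                f"signatures must differ at exactly one position, found {diffs}"
            )


@dataclass(frozen=True)
class ReadClassification:
    barcode_id: Optional[str]
    allele: Allele
    orientation: Literal["forward", "reverse"] = "forward"


@dataclass(frozen=True)
class BarcodeTally:
    """Per-barcode read counts and the derived mutation ratio (%)."""

    barcode_id: str
    n_wt: int
    n_mu: int
    n_ambiguous: int
    n_barcode_only: int
    ratio_percent: Optional[float]
    sufficient_depth: bool

    @property
    def n_informative(self) -> int:
        return self.n_wt + self.n_mu


@dataclass(frozen=True)
class TallyResult:
    """Per-barcode tallies plus pool-level bookkeeping."""

    barcodes: List[BarcodeTally]
    n_total: int
    n_unassigned: int  # reads without any panel barcode
    n_multi_barcode: int  # reads matching >= 2 distinct barcodes (chimeras)
    n_bad_records: int = 0  # unparseable FASTQ records, skipped

    def __getitem__(self, barcode_id: str) -> BarcodeTally:
        for t in self.barcodes:
            if t.barcode_id == barcode_id:
                return t
        raise KeyError(barcode_id)


def mutation_ratio_percent(n_wt: int, n_mu: int) -> Optional[float]:
    """100 * n_mu / (n_wt + n_mu), rounded half-up to one decimal.

    Undefined (None) when no informative reads were seen.
    """
    total = n_wt + n_mu
    if total == 0:
        return None
    exact = Decimal(100 * n_mu) / Decimal(total)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _occurs(pattern: str, text: str, max_mismatch: int) -> bool:
    if max_mismatch <= 0:
        return pattern in text
    res = edlib.align(pattern, text, mode="HW", task="distance", k=max_mismatch)
    return res["editDistance"] != -1


def _best_distance(pattern: str, text: str, max_mismatch: int) -> int:
    """Best infix edit distance of pattern in text, or -1 if above the
    tolerance (0 tolerance means exact substring search)."""
    if max_mismatch <= 0:
        return 0 if pattern in text else -1
    res = edlib.align(pattern, text, mode="HW", task="distance", k=max_mismatch)
    return res["editDistance"]


def classify_read(
    read: str,
    panel: Sequence[BarcodeSpec],
    sig: AlleleSignature,
    max_mismatch: int = 0,
    both_strands: bool = True,
) -> ReadClassification:
    """Assign one read to a barcode and an allele.

    The read and (when ``both_strands``) its reverse complement are
    scanned for every panel barcode; the orientation is the strand on
    which the barcode was found.  Reads hitting two or more distinct
    barcodes are chimera candidates and are classified ambiguous with no
    barcode.  Within the barcode's strand the allele is decided by the
    signatures: with exact matching (``max_mismatch = 0``) exactly one
    signature must occur -- both -> ambiguous, neither -> unassigned
    (barcode-only read).  With a nonzero tolerance the two signatures
    differ by less than the tolerance itself, so the read is assigned to
    the strictly nearer signature by edit distance; ties -> ambiguous.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    rc = reverse_complement(read) if both_strands else None
    hits: List[Tuple[str, str]] = []  # (barcode_id, orientation)
    for spec in panel:
        fwd = _occurs(spec.barcode_seq, read, max_mismatch)
        rev = rc is not None and _occurs(spec.barcode_seq, rc, max_mismatch)
        if fwd:
            hits.append((spec.barcode_id, "forward"))
        elif rev:
            hits.append((spec.barcode_id, "reverse"))
    if not hits:
        return ReadClassification(None, "unassigned", "forward")
    if len({bid for bid, _ in hits}) > 1:
        return ReadClassification(None, "ambiguous", hits[0][1])
    barcode_id, orientation = hits[0]
    oriented = read if orientation == "forward" else rc
    wt_d = _best_distance(sig.wt_signature, oriented, max_mismatch)
    mu_d = _best_distance(sig.mu_signature, oriented, max_mismatch)
    if wt_d == -1 and mu_d == -1:
        allele: Allele = "unassigned"
    elif mu_d == -1 or (wt_d != -1 and wt_d < mu_d):
        allele = "wt"
    elif wt_d == -1 or mu_d < wt_d:
        allele = "mu"
    else:
        allele = "ambiguous"
    return ReadClassification(barcode_id, allele, orientation)


ReadsInput = Union[str, Path, Iterable[str]]


def _iter_sequences(reads: ReadsInput) -> Tuple[Iterable[str], int]:
    """Yield plain sequences from a FASTQ path or an iterable of strings."""
    if isinstance(reads, (str, Path)):
        from blockamp.io import read_fastq_sequences

        return read_fastq_sequences(reads)
    return reads, 0


def tally(
    reads: ReadsInput,
    panel: Sequence[BarcodeSpec],
    sig: AlleleSignature,
    min_reads: int = 1000,
    max_mismatch: int = 0,
    both_strands: bool = True,
) -> TallyResult:
    """Count reads per barcode and allele over a read pool.

    ``reads`` may be a FASTQ path (plain or gzipped) or any iterable of
    sequence strings.  Returns one :class:`BarcodeTally` per panel
    barcode plus pool-level unassigned/chimera counts; the sum of all
    buckets equals the number of reads seen.
    """
    seqs, n_bad = _iter_sequences(reads)
    counts = {
        spec.barcode_id: {"wt": 0, "mu": 0, "ambiguous": 0, "unassigned": 0}
        for spec in panel
    }
    n_total = n_unassigned = n_multi = 0
    for seq in seqs:
        n_total += 1
        cls = classify_read(seq, panel, sig, max_mismatch, both_strands)
        if cls.barcode_id is None:
            if cls.allele == "ambiguous":
                n_multi += 1
            else:
                n_unassigned += 1
        else:
            counts[cls.barcode_id][cls.allele] += 1
    tallies = []
    for spec in panel:
        c = counts[spec.barcode_id]
        tallies.append(
            BarcodeTally(
                barcode_id=spec.barcode_id,
                n_wt=c["wt"],
                n_mu=c["mu"],
                n_ambiguous=c["ambiguous"],
                n_barcode_only=c["unassigned"],
                ratio_percent=mutation_ratio_percent(c["wt"], c["mu"]),
                sufficient_depth=(c["wt"] + c["mu"]) >= min_reads,
            )
        )
    return TallyResult(
        barcodes=tallies,
        n_total=n_total,
        n_unassigned=n_unassigned,
        n_multi_barcode=n_multi,
        n_bad_records=n_bad,
    )


def call_from_ratio(
    tally: BarcodeTally, positive_threshold_percent: float = 0.0
) -> Literal["positive", "negative", "insufficient"]:
    """Positive/negative call from a per-barcode mutation ratio.

    ``insufficient`` below the depth threshold; otherwise positive iff
    the ratio exceeds ``positive_threshold_percent`` (default 0.0, i.e.
    any rounded-nonzero mutant fraction counts as positive).
    """
    if not tally.sufficient_depth or tally.ratio_percent is None:
        return "insufficient"
    return (
        "positive"
        if tally.ratio_percent > positive_threshold_percent
        else "negative"
    )
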
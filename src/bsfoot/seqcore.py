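"""Sequence handling, inverted-repeat detection, hairpin folding and in-silico PCR.

Coordinates follow the 1-based inclusive convention used throughout yeast
genomics (an inverted repeat "from 1011 to 1049" includes both endpoints).
:class:`GenomicInterval` centralizes the conversion to Python's 0-based
half-open slices so the two conventions round-trip losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Watson-Crick pairs; G.T wobble is opt-in for the folder.
_WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = _WC_PAIRS | {("G", "T"), ("T", "G")}


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending record."""


class AmbiguousAmpliconError(ValueError):
    """Raised when an exact-match PCR has more than one possible product."""

    def __init__(self, amplicons: list["Amplicon"]):
        self.amplicons = amplicons
        spans = ", ".join(f"{a.interval.start}-{a.interval.end}" for a in amplicons)
        super().__init__(f"ambiguous PCR: {len(amplicons)} alternative products ({spans})")


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval on a linear sequence."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval {self.start}-{self.end} (1-based inclusive)")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def slice(self) -> slice:
        """0-based half-open slice covering the interval."""
        return slice(self.start - 1, self.end)

    @classmethod
    def from_slice(cls, start0: int, stop0: int, strand: str = "+") -> "GenomicInterval":
        return cls(start0 + 1, stop0, strand)


@dataclass(frozen=True)
class NucleotideSequence:
    """A named linear DNA sequence over {A,C,G,T,N}."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.bases) - ALPHABET
        if bad:
            raise ValueError(f"sequence {self.id!r} has illegal characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.bases)

    def subseq(self, interval: GenomicInterval) -> str:
        if interval.end > len(self):
            raise ValueError(f"interval {interval.start}-{interval.end} exceeds length {len(self)}")
        return self.bases[interval.slice()]

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(self.id, reverse_complement(self.bases))


@dataclass(frozen=True)
class IrAnnotation:
    """An inverted repeat: two equal-length arms around a loop.

    ``pairing_score`` counts the arm positions that actually base-pair
    (arm length minus mismatches).
    """

    left_arm: GenomicInterval
    right_arm: GenomicInterval
    loop: GenomicInterval
    arm_length: int
    mismatches: int
    pairing_score: int

    def __post_init__(self) -> None:
        if not (self.left_arm.end < self.loop.start <= self.loop.end < self.right_arm.start):
            raise ValueError("arms and loop out of order")
        if self.left_arm.length != self.right_arm.length or self.left_arm.length != self.arm_length:
            raise ValueError("arm lengths inconsistent")
        if self.pairing_score != self.arm_length - self.mismatches:
            raise ValueError("pairing_score must equal arm_length - mismatches")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.left_arm.start, self.right_arm.end)


@dataclass(frozen=True)
class HairpinFold:
    """A nested (pseudoknot-free) base pairing of a sequence.

    Pairs are 1-based (i, j) with i < j and j - i > min_loop.
    """

    pairs: frozenset[tuple[int, int]]
    n_pairs: int
    min_loop: int

    def __post_init__(self) -> None:
        if self.n_pairs != len(self.pairs):
            raise ValueError("n_pairs inconsistent with pairs")
        seen: set[int] = set()
        for i, j in self.pairs:
            if not i < j or j - i <= self.min_loop:
                raise ValueError(f"pair ({i},{j}) violates min_loop {self.min_loop}")
            if i in seen or j in seen:
                raise ValueError("position paired more than once")
            seen.update((i, j))
        for i, j in self.pairs:
            for k, l in self.pairs:
                if i < k < j < l:
                    raise ValueError("pseudoknotted pairs")


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str
    max_product: int = 10_000

    def __post_init__(self) -> None:
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not 15 <= len(p) <= 35:
                raise ValueError(f"{name} primer must be 15-35 nt, got {len(p)}")
            bad = set(p) - ALPHABET
            if bad:
                raise ValueError(f"{name} primer has illegal characters {sorted(bad)}")


@dataclass(frozen=True)
class Amplicon:
    interval: GenomicInterval | None
    length: int
    amplifiable: bool


@dataclass(frozen=True)
class MbnPcrResult:
    """Outcome of an in-silico mung-bean-nuclease + PCR assay."""

    amplifiable: bool
    cut_hairpins: tuple[IrAnnotation, ...]


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read FASTA records, uppercasing and converting U to T.

    Raises :class:`FastaParseError` naming the record on illegal characters,
    and for files with no records.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaParseError(f"no FASTA records in {path}")
    out = []
    for rec in records:
        bases = str(rec.seq).upper().replace("U", "T")
        try:
            out.append(NucleotideSequence(rec.id, bases))
        except ValueError as exc:
            raise FastaParseError(f"record {rec.id!r}: {exc}") from exc
    return out


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.bases), 70):
                fh.write(s.bases[i : i + 70] + "\n")


def reverse_complement(seq: str) -> str:
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(f"illegal characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def _pairs_wc(a: str, b: str) -> bool:
    return (a, b) in _WC_PAIRS


def find_inverted_repeats(
    seq: NucleotideSequence | str,
    min_arm: int = 6,
    max_loop: int = 10,
    max_mismatch: int = 0,
    min_loop: int = 3,
) -> list[IrAnnotation]:
    """Find maximal inverted repeats.

    An annotation with left arm ``s[i..i+a-1]``, loop of length ``g`` and right
    arm ``s[j..j+a-1]`` is *valid* when (in pairing order) every arm position t
    pairs ``s[i+a-1-t]`` against ``s[j+t]`` with at most ``max_mismatch``
    non-Watson-Crick pairs, the innermost and outermost pairs both match,
    ``a >= min_arm`` and ``min_loop <= g <= max_loop``.  It is *maximal* (and
    reported) when neither one-step extension is valid: growing both arms
    outward (same loop) nor inward (loop shrinks by 2).  Results are sorted by
    left-arm start, then descending arm length.
    """
    s = seq.bases if isinstance(seq, NucleotideSequence) else seq
    if min_arm < 4:
        raise ValueError("min_arm must be >= 4")
    if max_loop < min_loop:
        raise ValueError(f"max_loop must be >= min_loop ({min_loop})")
    n = len(s)
    out: list[IrAnnotation] = []
    # Enumerate loop centers: e = 0-based index of innermost left-arm base,
    # f = innermost right-arm base; loop g = f - e - 1.
    for e in range(n - 1):
        for g in range(min_loop, max_loop + 1):
            f = e + g + 1
            if f >= n:
                break
            if not _pairs_wc(s[e], s[f]):
                continue  # innermost pair must match
            # Extend outward; t indexes the pair (s[e-t], s[f+t]).
            mism_at: list[bool] = []
            t = 0
            budget_left = max_mismatch
            while e - t >= 0 and f + t < n:
                ok = _pairs_wc(s[e - t], s[f + t])
                if not ok:
                    if budget_left == 0:
                        break
                    budget_left -= 1
                mism_at.append(not ok)
                t += 1
            max_a = t  # longest arm with cumulative mismatches <= budget
            if max_a < min_arm:
                continue
            cum = 0
            cum_mism = []
            for flag in mism_at:
                cum += flag
                cum_mism.append(cum)
            inward_ok = (
                g - 2 >= min_loop
                and e + 1 < f - 1
                and _pairs_wc(s[e + 1], s[f - 1])
            )
            for a in range(min_arm, max_a + 1):
                if mism_at[a - 1]:
                    continue  # outermost pair must match
                m = cum_mism[a - 1]
                # outward extension valid iff next pair exists, matches or fits
                # budget, and its own outermost pair matches -> only a matching
                # next pair extends (a mismatching one breaks the terminal rule)
                if a < max_a and not mism_at[a]:
                    continue  # outward-extendable
                if inward_ok:
                    continue  # inward-extendable (mismatch count unchanged)
                left = GenomicInterval(e - a + 2, e + 1)
                right = GenomicInterval(f + 1, f + a)
                loop_iv = GenomicInterval(e + 2, f)
                out.append(
                    IrAnnotation(left, right, loop_iv, a, m, a - m)
                )
    out.sort(key=lambda ir: (ir.left_arm.start, -ir.arm_length, ir.loop.length))
    return out


def fold_hairpin(seq: str, min_loop: int = 3, wobble: bool = False) -> HairpinFold:
    """Maximum nested base pairing (Nussinov) with a minimum loop length.

    Watson-Crick pairs only by default; set ``wobble`` to allow G.T pairs.
    Raises ValueError for sequences shorter than ``min_loop + 2``.
    """
    n = len(seq)
    if n < min_loop + 2:
        raise ValueError(f"sequence of length {n} too short to fold (min {min_loop + 2})")
    pairs_ok = _WOBBLE_PAIRS if wobble else _WC_PAIRS
    # dp[i][j]: max pairs in seq[i..j] (0-based inclusive)
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i][j - 1]  # j unpaired
            for k in range(i, j - min_loop):
                if (seq[k], seq[j]) in pairs_ok:
                    left = dp[i][k - 1] if k > i else 0
                    inner = dp[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    cand = left + inner + 1
                    if cand > best:
                        best = cand
            dp[i][j] = best
    pairs: set[tuple[int, int]] = set()

    def traceback(i: int, j: int) -> None:
        while j - i > min_loop:
            if dp[i][j] == dp[i][j - 1]:
                j -= 1
                continue
            for k in range(i, j - min_loop):
                if (seq[k], seq[j]) in pairs_ok:
                    left = dp[i][k - 1] if k > i else 0
                    inner = dp[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    if left + inner + 1 == dp[i][j]:
                        pairs.add((k + 1, j + 1))
                        if k > i:
                            traceback(i, k - 1)
                        i, j = k + 1, j - 1
                        break
            else:  # pragma: no cover - dp guarantees a branch above
                raise AssertionError("traceback failed")

    traceback(0, n - 1)
    return HairpinFold(frozenset(pairs), len(pairs), min_loop)


_STEM_BREAK = str.maketrans("ACGT", "CATG")

#: Element coordinates of the loop point substitutions (1-based): the single
#: substitution kind changes position 1027; the triple kind changes 1025,
#: 1027 and 1029, all to C.
LOOP_1C_POSITIONS = (1027,)
LOOP_3C_POSITIONS = (1025, 1027, 1029)


def apply_ir_mutation(
    seq: NucleotideSequence,
    ir: IrAnnotation,
    kind: str,
    substitutions: dict[int, str] | None = None,
    required_drop_fraction: float = 1.0,
) -> NucleotideSequence:
    """Mutate the IR of ``seq``.

    kinds:
      - ``stem_mt``: substitute every right-arm base with a non-pairing base
        (A<->C, G<->T), destroying the stem; verified to drop the hairpin
        pairing score below ``required_drop_fraction`` x wild type.
      - ``loop_1C`` / ``loop_3C``: point substitutions to C at element
        coordinates 1027 / (1025, 1027, 1029); positions must fall inside the
        IR span.
      - ``custom``: apply ``substitutions`` ({1-based position: base}); empty
        mapping is the identity.
    """
    bases = list(seq.bases)

    def _subst(pos: int, base: str) -> None:
        if not 1 <= pos <= len(bases):
            raise ValueError(f"position {pos} outside sequence of length {len(bases)}")
        bases[pos - 1] = base

    if kind == "stem_mt":
        wt_score = fold_hairpin(seq.subseq(ir.span)).n_pairs
        arm = seq.subseq(ir.right_arm).translate(_STEM_BREAK)
        for off, b in enumerate(arm):
            _subst(ir.right_arm.start + off, b)
        mutant = NucleotideSequence(seq.id + "_stem_mt", "".join(bases))
        mt_score = fold_hairpin(mutant.subseq(ir.span)).n_pairs
        if mt_score >= required_drop_fraction * wt_score:
            raise ValueError(
                f"stem mutation failed to weaken hairpin ({mt_score} vs WT {wt_score})"
            )
        return mutant
    if kind in {"loop_1C", "loop_3C"}:
        positions = LOOP_1C_POSITIONS if kind == "loop_1C" else LOOP_3C_POSITIONS
        for pos in positions:
            if not ir.span.start <= pos <= ir.span.end:
                raise ValueError(f"loop mutation position {pos} outside IR span")
            _subst(pos, "C")
        return NucleotideSequence(seq.id + f"_{kind}", "".join(bases))
    if kind == "custom":
        for pos, base in (substitutions or {}).items():
            if base not in ALPHABET:
                raise ValueError(f"illegal base {base!r}")
            _subst(pos, base)
        return NucleotideSequence(seq.id, "".join(bases))
    raise ValueError(f"unknown mutation kind {kind!r}")


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def in_silico_pcr(template: NucleotideSequence, primers: PrimerPair) -> Amplicon:
    """Exact-match PCR: forward binds the top strand, reverse the bottom.

    Returns an unamplifiable :class:`Amplicon` when no product exists within
    ``max_product``; raises :class:`AmbiguousAmpliconError` when more than one
    primer-site pairing yields a product.
    """
    fwd_sites = _find_all(template.bases, primers.forward)
    rev_sites = _find_all(template.bases, reverse_complement(primers.reverse))
    products: list[Amplicon] = []
    for f in fwd_sites:
        for r in rev_sites:
            if r < f + len(primers.forward):
                continue  # reverse site must be downstream of the forward site
            length = r + len(primers.reverse) - f
            if length <= primers.max_product:
                iv = GenomicInterval(f + 1, r + len(primers.reverse))
                products.append(Amplicon(iv, length, True))
    if not products:
        return Amplicon(None, 0, False)
    if len(products) > 1:
        raise AmbiguousAmpliconError(products)
    return products[0]


def mbn_pcr_predict(
    template: NucleotideSequence,
    primers: PrimerPair,
    fold_threshold: int = 12,
    min_arm: int = 10,
    max_loop: int = 10,
    max_mismatch: int = 1,
) -> MbnPcrResult:
    """Predict a mung-bean-nuclease + PCR readout.

    MBN cleaves the single-stranded loop of an extruded cruciform, so the
    template is not amplifiable when a detected IR inside the amplicon folds
    into at least ``fold_threshold`` base pairs.  Single-threshold cleavage on
    the Nussinov pairing score stands in for a thermodynamic extrusion model.
    """
    amplicon = in_silico_pcr(template, primers)
    if not amplicon.amplifiable:
        return MbnPcrResult(False, ())
    assert amplicon.interval is not None
    hairpins = []
    for ir in find_inverted_repeats(template, min_arm, max_loop, max_mismatch):
        if ir.span.start < amplicon.interval.start or ir.span.end > amplicon.interval.end:
            continue
        if fold_hairpin(template.subseq(ir.span)).n_pairs >= fold_threshold:
            hairpins.append(ir)
    return MbnPcrResult(not hairpins, tuple(hairpins))


def irs_to_tsv(seq_id: str, irs: Sequence[IrAnnotation]) -> str:
    """BED-like 1-based TSV: seqid  start  end  kind  score."""
    lines = ["seqid\tstart\tend\tkind\tscore"]
    for ir in irs:
        lines.append(
            f"{seq_id}\t{ir.span.start}\t{ir.span.end}\t"
            f"IR_arm{ir.arm_length}_loop{ir.loop.length}_mm{ir.mismatches}\t{ir.pairing_score}"
        )
    return "\n".join(lines) + "\n"
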
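"""Generators for every input the analysis consumes, with known ground truth.

The central generator emulates non-denaturing bisulfite sequencing of
chromatinized DNA: molecules are double stranded, so a cytosine is converted
to thymine only while transiently exposed as ssDNA.  Exposure probability is
a two-regime step function of position (high upstream of a planted inverted
repeat, low downstream), mirroring a chromatin boundary.  Reads sample both
strands; a bottom-strand molecule converts its own cytosines, which sit under
top-strand guanine positions.  Conversion is attenuated by the bisulfite
conversion efficiency and reads carry independent substitution sequencing
errors.  Everything is seeded and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .seqcore import (
    GenomicInterval,
    IrAnnotation,
    NucleotideSequence,
    find_inverted_repeats,
    reverse_complement,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_A, _CODE_C, _CODE_G, _CODE_T = 0, 1, 2, 3
_DECODE = {0: "A", 1: "C", 2: "G", 3: "T"}


def encode(seq: str) -> np.ndarray:
    """Map ACGT to int8 codes 0..3 (N -> 4)."""
    lut = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode()


@dataclass(frozen=True)
class ExposureModel:
    """Two-regime per-molecule ssDNA exposure along an element.

    Positions strictly upstream of ``boundary_pos`` (1-based) are exposed with
    probability ``p_up`` per cytosine per molecule, positions at or downstream
    with ``p_down``.  An exposed cytosine converts with probability
    ``conv_eff``.  ``correlation_mode`` 'per_base' draws exposure independently
    per cytosine; 'per_molecule_segment' draws contiguous exposed patches along
    each molecule (real ssDNA exposure is correlated along a molecule).
    """

    boundary_pos: int
    p_up: float = 0.20
    p_down: float = 0.04
    conv_eff: float = 1.0
    seq_error: float = 0.0
    correlation_mode: str = "per_base"
    segment_persistence: float = 0.98  # per-base state persistence in segment mode

    def __post_init__(self) -> None:
        for name in ("p_up", "p_down", "conv_eff", "seq_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.correlation_mode not in {"per_base", "per_molecule_segment"}:
            raise ValueError(f"unknown correlation_mode {self.correlation_mode!r}")

    def exposure_at(self, positions: np.ndarray) -> np.ndarray:
        """True exposure probability at 1-based positions."""
        return np.where(np.asarray(positions) < self.boundary_pos, self.p_up, self.p_down)


@dataclass(frozen=True)
class ReadSimConfig:
    n_reads: int
    read_length: int = 250
    paired: bool = False
    strand_fraction_top: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be > 0")
        if not 0.0 <= self.strand_fraction_top <= 1.0:
            raise ValueError("strand_fraction_top must be in [0,1]")


@dataclass
class SimTruth:
    """Ground truth of a bisulfite read simulation.

    ``reads`` has one row per read: read_id, origin_pos (1-based top
    coordinate of the leftmost covered base), strand (top/bottom),
    n_converted.  ``per_position`` has the true exposure probability plus the
    realized converted/covered counts per strand at each position, in top
    coordinates (top rows at reference C, bottom rows at reference G).
    """

    reads: pd.DataFrame
    per_position: pd.DataFrame

    def to_read_tsv(self) -> str:
        return self.reads.to_csv(sep="\t", index=False)

    def to_position_tsv(self) -> str:
        return self.per_position.to_csv(sep="\t", index=False)


def simulate_ty1_like_reference(
    length: int,
    ir_spec: dict,
    gc_content: float = 0.40,
    seed: int = 0,
) -> tuple[NucleotideSequence, IrAnnotation]:
    """Random reference with a planted inverted repeat.

    ``ir_spec`` needs ``arm``, ``loop`` and ``position`` (1-based start of the
    left arm).  The planted IR is verified with the detector; the background
    is resampled (deterministically, from the same seeded stream) until the
    detector reports exactly the planted repeat, so spurious same-strength
    repeats never shadow the ground truth.
    """
    arm, loop, pos = ir_spec["arm"], ir_spec["loop"], ir_spec["position"]
    if arm < 4 or loop < 3 or pos < 1:
        raise ValueError(f"infeasible IR geometry: arm={arm} loop={loop} position={pos}")
    span = 2 * arm + loop
    if pos + span - 1 > length:
        raise ValueError(
            f"infeasible IR geometry: IR spans {pos}-{pos + span - 1} but length is {length}"
        )
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2])
    for _attempt in range(200):
        codes = rng.choice(4, size=length, p=p).astype(np.int8)
        bases = list(decode(codes))
        left = "".join(rng.choice(list("ACGT"), size=arm, p=p))
        loop_seq = "".join(rng.choice(list("ACGT"), size=loop, p=p))
        planted = left + loop_seq + reverse_complement(left)
        bases[pos - 1 : pos - 1 + span] = planted
        seq = NucleotideSequence(f"ty1like_{length}_{seed}", "".join(bases))
        found = find_inverted_repeats(seq, min_arm=arm, max_loop=loop, max_mismatch=0, min_loop=3)
        expected = (pos, pos + arm - 1, pos + arm + loop, pos + span - 1)
        if len(found) == 1 and (
            found[0].left_arm.start,
            found[0].left_arm.end,
            found[0].right_arm.start,
            found[0].right_arm.end,
        ) == expected:
            ir = found[0]
            return seq, ir
    raise RuntimeError("could not plant a uniquely detectable IR; geometry too permissive")


def simulate_bisulfite_reads(
    ref: NucleotideSequence,
    model: ExposureModel,
    config: ReadSimConfig,
) -> tuple[list[tuple[str, str]], SimTruth]:
    """Simulate non-denaturing bisulfite reads from both strands.

    Returns ``(reads, truth)`` where reads are ``(read_id, sequence)`` tuples
    (5'->3' on the strand of origin; bottom-strand reads therefore appear
    reverse-complemented relative to top coordinates).  Use
    :func:`reads_to_fastq` to serialize.
    """
    L = len(ref)
    rl = config.read_length
    if rl > L:
        raise ValueError(f"read_length {rl} exceeds reference length {L}")
    rng = np.random.default_rng(config.seed)
    n = config.n_reads
    ref_codes = encode(ref.bases)

    starts = rng.integers(0, L - rl + 1, size=n)  # 0-based leftmost position
    is_top = rng.random(n) < config.strand_fraction_top

    offsets = np.arange(rl)
    pos0 = starts[:, None] + offsets[None, :]  # (n, rl) 0-based top coords
    read_codes = ref_codes[pos0].copy()
    # bottom-strand molecules: complement then reverse to 5'->3'
    bot = ~is_top
    read_codes[bot] = (3 - read_codes[bot])[:, ::-1]
    pos0_strandwise = pos0.copy()
    pos0_strandwise[bot] = pos0[bot][:, ::-1]

    # cytosines of the strand of origin
    is_c = read_codes == _CODE_C
    p_true = model.exposure_at(pos0_strandwise + 1)
    if model.correlation_mode == "per_base":
        exposed = rng.random((n, rl)) < p_true
    else:
        exposed = _segment_exposure(rng, p_true, model.segment_persistence)
    converted = is_c & exposed & (rng.random((n, rl)) < model.conv_eff)
    read_codes[converted] = _CODE_T

    # per-position realized truth (before sequencing error), top coordinates
    per_pos = _tally_truth(ref_codes, pos0_strandwise, is_top, is_c, converted, model)

    if model.seq_error > 0:
        err = rng.random((n, rl)) < model.seq_error
        shift = rng.integers(1, 4, size=int(err.sum()))
        read_codes[err] = (read_codes[err] + shift) % 4

    n_conv = converted.sum(axis=1)
    seqs = _codes_to_strings(read_codes)
    ids = [f"read{i:06d}" for i in range(n)]
    reads = list(zip(ids, seqs))
    truth_reads = pd.DataFrame(
        {
            "read_id": ids,
            "origin_pos": starts + 1,
            "strand": np.where(is_top, "top", "bottom"),
            "n_converted": n_conv,
        }
    )
    return reads, SimTruth(truth_reads, per_pos)


def _segment_exposure(rng: np.random.Generator, p: np.ndarray, rho: float) -> np.ndarray:
    """Markov exposure: keep the previous state w.p. rho, else redraw
    Bernoulli(p at the current base).  Marginal stays ~p; exposure comes in
    contiguous patches with mean length ~1/(1-rho)."""
    n, rl = p.shape
    redraw = rng.random((n, rl)) >= rho
    redraw[:, 0] = True
    draws = rng.random((n, rl)) < p
    # forward-fill non-redraw positions with the last redraw outcome
    idx = np.where(redraw, np.arange(rl)[None, :], 0)
    idx = np.maximum.accumulate(idx, axis=1)
    return np.take_along_axis(draws, idx, axis=1)


def _tally_truth(
    ref_codes: np.ndarray,
    pos0_strandwise: np.ndarray,
    is_top: np.ndarray,
    is_c: np.ndarray,
    converted: np.ndarray,
    model: ExposureModel,
) -> pd.DataFrame:
    L = len(ref_codes)
    cov = np.zeros((2, L), dtype=np.int64)  # row 0 top, 1 bottom
    conv = np.zeros((2, L), dtype=np.int64)
    for row, mask in ((0, is_top), (1, ~is_top)):
        if not mask.any():
            continue
        flat_pos = pos0_strandwise[mask][is_c[mask]]
        np.add.at(cov[row], flat_pos, 1)
        flat_conv = pos0_strandwise[mask][converted[mask]]
        np.add.at(conv[row], flat_conv, 1)
    rows = []
    top_c = np.where(ref_codes == _CODE_C)[0]
    bot_c = np.where(ref_codes == _CODE_G)[0]  # bottom-strand C under top G
    for strand, row, posset in (("top", 0, top_c), ("bottom", 1, bot_c)):
        pos1 = posset + 1
        rows.append(
            pd.DataFrame(
                {
                    "pos": pos1,
                    "strand": strand,
                    "p_exposure": model.exposure_at(pos1),
                    "covered": cov[row, posset],
                    "converted": conv[row, posset],
                }
            )
        )
    return pd.concat(rows, ignore_index=True).sort_values(["pos", "strand"], ignore_index=True)


def _codes_to_strings(codes: np.ndarray) -> list[str]:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    ascii_rows = lut[codes]
    return [row.tobytes().decode() for row in ascii_rows]


def inject_indel_reads(
    reads: list[tuple[str, str]],
    fraction: float,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], set[str]]:
    """Corrupt a fraction of reads with a 1-nt indel (the filtered class).

    Returns the corrupted read list and the set of corrupted read ids.
    """
    rng = np.random.default_rng(seed)
    out = []
    corrupted: set[str] = set()
    for rid, s in reads:
        if rng.random() < fraction and len(s) > 2:
            i = int(rng.integers(1, len(s) - 1))
            if rng.random() < 0.5:
                s = s[:i] + s[i + 1 :]  # deletion
            else:
                s = s[:i] + "ACGT"[int(rng.integers(4))] + s[i:]  # insertion
            corrupted.add(rid)
        out.append((rid, s))
    return out, corrupted


def reads_to_fastq(reads: Sequence[tuple[str, str]], path, quality: int = 40) -> None:
    """Write reads as FASTQ with a constant quality."""
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        for rid, s in reads:
            fh.write(f"@{rid}\n{s}\n+\n{qchar * len(s)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def simulate_chip_tracks(
    n_elements: int,
    profile: Callable[[np.ndarray], np.ndarray] | np.ndarray,
    noise_sd: float,
    seed: int = 0,
    window: tuple[int, int] = (0, 2000),
) -> list["OccupancyTrack"]:
    """Per-element occupancy = profile + iid Gaussian noise, truncated at 0."""
    from .chromatin import OccupancyTrack

    rng = np.random.default_rng(seed)
    positions = np.arange(window[0], window[1])
    base = profile(positions) if callable(profile) else np.asarray(profile, dtype=float)
    if base.shape != positions.shape:
        raise ValueError("profile length does not match window")
    tracks = []
    for i in range(n_elements):
        vals = np.clip(base + rng.normal(0.0, noise_sd, size=base.shape), 0.0, None)
        tracks.append(OccupancyTrack(f"element_{i:03d}", window[0], vals))
    return tracks


DEFAULT_CQ_INTERCEPT = 20.0


def simulate_qpcr(
    true_quantity,
    efficiency: float = 2.0,
    cq_noise_sd: float = 0.0,
    seed: int = 0,
    intercept: float = DEFAULT_CQ_INTERCEPT,
):
    """Cq = intercept - log_efficiency(quantity) + noise.

    Unit quantity amplifies to threshold at ``intercept`` cycles; each halving
    costs one extra cycle at efficiency 2.
    """
    q = np.asarray(true_quantity, dtype=float)
    if np.any(q <= 0):
        raise ValueError("true_quantity must be > 0")
    if efficiency <= 1:
        raise ValueError("efficiency must be > 1")
    rng = np.random.default_rng(seed)
    cq = intercept - np.log(q) / np.log(efficiency)
    if cq_noise_sd > 0:
        cq = cq + rng.normal(0.0, cq_noise_sd, size=cq.shape)
    return float(cq) if cq.ndim == 0 else cq
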
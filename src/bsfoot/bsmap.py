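"""Bisulfite-aware read alignment, filtering, base counting and CT conversion rates.

Alignment uses the standard three-letter reduction for bisulfite data: a read
from the top strand is compared with C collapsed to T in both read and
reference (conversions then score as matches), a read from the bottom strand
with G collapsed to A (its converted cytosines surface as A under top-strand
coordinates).  Each read is scored at every offset in both collapse modes and
both orientations; the best placement wins, and a tie for best anywhere marks
the read ambiguous -- the multi-mapping class that a MAPQ filter would remove.

Scoring is ungapped by default (matches are counted with a one-hot matrix
product, so a batch of reads scores all offsets at once).  An optional gapped
mode rescues reads the ungapped scan rejects via banded edit-distance
alignment and records indel edit ops, which the downstream filter removes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqcore import NucleotideSequence
from .synthetic import encode, decode

_CODE_A, _CODE_C, _CODE_G, _CODE_T = 0, 1, 2, 3

TOP, BOTTOM = "top", "bottom"


@dataclass
class BisulfiteAlignment:
    """One aligned read in top-strand coordinates.

    ``edit_ops`` is a CIGAR-like list of (op, length) with op in
    {'M' match/mismatch, 'I' insertion, 'D' deletion} spanning the read.
    ``read_codes_top`` holds the observed bases (0..3 = ACGT) oriented along
    the top strand, so counting never needs the raw read again.
    """

    read_id: str
    ref_start: int  # 1-based
    mapped_strand: str  # 'top' | 'bottom'
    edit_ops: list[tuple[str, int]]
    ambiguity_flag: bool
    reverse_complemented: bool
    n_mismatch: int
    read_codes_top: np.ndarray

    @property
    def has_indel(self) -> bool:
        return any(op in ("I", "D") for op, _ in self.edit_ops)


@dataclass
class BaseCountMatrix:
    """Per-position A/C/G/T counts in top coordinates, split by mapped strand."""

    ref_id: str
    counts: dict  # strand -> (L, 4) int64 array

    @property
    def length(self) -> int:
        return self.counts[TOP].shape[0]

    def to_tsv(self) -> str:
        rows = ["pos\tstrand\tA\tC\tG\tT"]
        for strand in (TOP, BOTTOM):
            c = self.counts[strand]
            for pos in range(c.shape[0]):
                a, cc, g, t = c[pos]
                rows.append(f"{pos + 1}\t{strand}\t{a}\t{cc}\t{g}\t{t}")
        return "\n".join(rows) + "\n"


@dataclass
class ConversionProfile:
    """Strand-specific CT conversion rates.

    ``table`` columns: pos (1-based), strand, n_converted, depth, rate_pct
    (NaN when depth < min_depth).  Top-strand rows exist only at reference C
    positions, bottom-strand rows only at reference G positions.
    """

    table: pd.DataFrame
    min_depth: int

    def to_tsv(self) -> str:
        out = self.table[["pos", "strand", "rate_pct", "depth"]]
        return out.to_csv(sep="\t", index=False, float_format="%.6g")

    def pooled(self) -> pd.DataFrame:
        """Strand-pooled counts per position (sum of converted and depths)."""
        g = self.table.groupby("pos", as_index=False)[["n_converted", "depth"]].sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            g["rate_pct"] = np.where(
                g["depth"] > 0, 100.0 * g["n_converted"] / g["depth"], np.nan
            )
        return g


def _collapse(codes: np.ndarray, mode: str) -> np.ndarray:
    out = codes.copy()
    if mode == TOP:
        out[out == _CODE_C] = _CODE_T
    else:
        out[out == _CODE_G] = _CODE_A
    return out


def _onehot(codes: np.ndarray) -> np.ndarray:
    """(..., 4) float32 one-hot; N (code 4) maps to all-zero (never matches)."""
    eye = np.zeros((5, 4), dtype=np.float32)
    eye[:4] = np.eye(4, dtype=np.float32)
    return eye[codes]


def align_bisulfite_reads(
    reads: Iterable[tuple[str, str]],
    ref: NucleotideSequence,
    max_mismatch_frac: float = 0.1,
    gapped: bool = False,
    batch_size: int = 2000,
) -> list[BisulfiteAlignment]:
    """Align reads to a single reference under bisulfite three-letter matching.

    Reads failing the mismatch threshold in every placement are dropped
    (or, with ``gapped=True``, retried with a gapped aligner whose indel
    alignments are recorded and left for :func:`filter_alignments`).
    Ties for best score across placements set ``ambiguity_flag``.
    Raises ValueError for a read longer than the reference.
    """
    read_list = [(rid, s) for rid, s in reads]
    L = len(ref)
    for rid, s in read_list:
        if len(s) > L:
            raise ValueError(f"read {rid} ({len(s)} nt) longer than reference ({L} nt)")
    ref_codes = encode(ref.bases)
    ref_oh = {mode: _onehot(_collapse(ref_codes, mode)) for mode in (TOP, BOTTOM)}

    # group reads by length so each batch is a rectangular array
    by_len: dict[int, list[int]] = {}
    for i, (_, s) in enumerate(read_list):
        by_len.setdefault(len(s), []).append(i)

    alignments: list[BisulfiteAlignment] = []
    for rl, idxs in by_len.items():
        n_off = L - rl + 1
        windows = {
            mode: np.lib.stride_tricks.sliding_window_view(ref_oh[mode], rl, axis=0)
            for mode in (TOP, BOTTOM)
        }  # (n_off, 4, rl)
        for bstart in range(0, len(idxs), batch_size):
            bidx = idxs[bstart : bstart + batch_size]
            fwd = np.stack([encode(read_list[i][1]) for i in bidx])
            rev = (np.where(fwd < 4, 3 - fwd, 4))[:, ::-1]
            alignments.extend(
                _align_batch(
                    [read_list[i] for i in bidx],
                    fwd,
                    rev,
                    windows,
                    ref_codes,
                    rl,
                    max_mismatch_frac,
                    gapped,
                )
            )
    alignments.sort(key=lambda a: a.read_id)
    return alignments


def _align_batch(
    batch: list[tuple[str, str]],
    fwd: np.ndarray,
    rev: np.ndarray,
    windows: dict,
    ref_codes: np.ndarray,
    rl: int,
    max_mismatch_frac: float,
    gapped: bool,
) -> list[BisulfiteAlignment]:
    B = fwd.shape[0]
    # A placement is an (offset, orientation) pair.  Each orientation is
    # scored under both collapse modes; a mode tie at one placement is not
    # multi-mapping (an unconverted read is mode-agnostic) and resolves to the
    # orientation-consistent mode of the directional protocol (forward reads
    # derive from the top strand, reverse-complemented reads from the bottom).
    orient_scores = []  # per orientation: (scores (B, n_off) int, mode array)
    for codes, consistent_mode in ((fwd, TOP), (rev, BOTTOM)):
        per_mode = {}
        for mode in (TOP, BOTTOM):
            oh = _onehot(_collapse(codes, mode))  # (B, rl, 4)
            w = windows[mode]  # (n_off, 4, rl)
            s = oh.reshape(B, rl * 4) @ w.transpose(0, 2, 1).reshape(-1, rl * 4).T
            per_mode[mode] = np.rint(s).astype(np.int32)
        other = BOTTOM if consistent_mode == TOP else TOP
        scores = np.maximum(per_mode[consistent_mode], per_mode[other])
        mode_is_consistent = per_mode[consistent_mode] >= per_mode[other]
        orient_scores.append((scores, mode_is_consistent, consistent_mode, other))

    s_fwd, s_rev = orient_scores[0][0], orient_scores[1][0]
    best_per_orient = np.stack([s_fwd.max(axis=1), s_rev.max(axis=1)])  # (2, B)
    best = best_per_orient.max(axis=0)
    n_best = (s_fwd == best[:, None]).sum(axis=1) + (s_rev == best[:, None]).sum(axis=1)

    out = []
    max_mm = int(np.floor(max_mismatch_frac * rl))
    for b, (rid, _seq) in enumerate(batch):
        n_mm = rl - int(best[b])
        if n_mm > max_mm:
            if gapped:
                aln = _align_gapped(rid, fwd[b], rev[b], ref_codes, max_mm)
                if aln is not None:
                    out.append(aln)
            continue
        oi = 0 if best_per_orient[0, b] == best[b] else 1
        scores, mode_is_consistent, consistent_mode, other = orient_scores[oi]
        off = int(scores[b].argmax())
        mode = consistent_mode if mode_is_consistent[b, off] else other
        codes = fwd if oi == 0 else rev
        out.append(
            BisulfiteAlignment(
                read_id=rid,
                ref_start=off + 1,
                mapped_strand=mode,
                edit_ops=[("M", rl)],
                ambiguity_flag=bool(n_best[b] > 1),
                reverse_complemented=bool(oi == 1),
                n_mismatch=n_mm,
                read_codes_top=codes[b].copy(),
            )
        )
    return out


def _align_gapped(
    rid: str,
    fwd: np.ndarray,
    rev: np.ndarray,
    ref_codes: np.ndarray,
    max_edits: int,
) -> BisulfiteAlignment | None:
    """Infix gapped alignment on collapsed strings via edit distance (edlib)."""
    import edlib

    candidates = []
    for codes, mode, rc in (
        (fwd, TOP, False),
        (rev, TOP, True),
        (fwd, BOTTOM, False),
        (rev, BOTTOM, True),
    ):
        q = decode(_collapse(codes, mode))
        t = decode(_collapse(ref_codes.copy(), mode))
        res = edlib.align(q, t, mode="HW", task="path", k=max_edits)
        if res["editDistance"] >= 0:
            candidates.append((res["editDistance"], res, codes, mode, rc))
    if not candidates:
        return None
    candidates.sort(key=lambda c: c[0])
    dist, res, codes, mode, rc = candidates[0]
    ambiguous = len(res["locations"]) > 1 or (
        len(candidates) > 1 and candidates[1][0] == dist
    )
    start = res["locations"][0][0]
    ops = _parse_cigar(res["cigar"])
    return BisulfiteAlignment(
        read_id=rid,
        ref_start=start + 1,
        mapped_strand=mode,
        edit_ops=ops,
        ambiguity_flag=ambiguous,
        reverse_complemented=rc,
        n_mismatch=dist,
        read_codes_top=codes.copy(),
    )


def _parse_cigar(cigar: str) -> list[tuple[str, int]]:
    ops, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            op = "M" if ch in "=XM" else ch
            if ops and ops[-1][0] == op:
                ops[-1] = (op, ops[-1][1] + int(num))
            else:
                ops.append((op, int(num)))
            num = ""
    return ops


def filter_alignments(alignments: Sequence[BisulfiteAlignment]) -> list[BisulfiteAlignment]:
    """Drop ambiguous (multi-mapping) alignments and any with indel edit ops.

    This is the analysis's analog of removing low-MAPQ reads and indel reads;
    order is preserved.
    """
    return [a for a in alignments if not a.ambiguity_flag and not a.has_indel]


def count_bases(
    alignments: Sequence[BisulfiteAlignment],
    ref: NucleotideSequence,
) -> BaseCountMatrix:
    """Count observed bases per position in top coordinates, by mapped strand.

    Counts are raw: a mismatch to neither C nor T still increments its base
    column.  Indel-containing alignments are not countable here (filter first).
    """
    L = len(ref)
    counts = {s: np.zeros((L, 4), dtype=np.int64) for s in (TOP, BOTTOM)}
    pos_by_strand = {TOP: ([], []), BOTTOM: ([], [])}
    for a in alignments:
        if a.has_indel:
            raise ValueError(f"alignment {a.read_id} has indels; filter before counting")
        rl = a.read_codes_top.shape[0]
        pos, codes = pos_by_strand[a.mapped_strand]
        pos.append(np.arange(a.ref_start - 1, a.ref_start - 1 + rl))
        codes.append(a.read_codes_top)
    for strand, (pos, codes) in pos_by_strand.items():
        if not pos:
            continue
        p = np.concatenate(pos)
        c = np.concatenate(codes)
        valid = c < 4
        np.add.at(counts[strand], (p[valid], c[valid]), 1)
    return BaseCountMatrix(ref.id, counts)


def conversion_profile(
    counts: BaseCountMatrix,
    ref: NucleotideSequence,
    min_depth: int = 10,
) -> ConversionProfile:
    """Strand-specific CT conversion rates (%).

    Top strand at every reference C: 100 * T / (C + T) from top-partition
    counts; bottom strand at every reference G: 100 * A / (G + A) from the
    bottom partition.  Other bases never enter the denominator.  Rates are NaN
    where the denominator is below ``min_depth``.
    """
    if counts.length != len(ref):
        raise ValueError("count matrix and reference lengths differ")
    ref_codes = encode(ref.bases)
    frames = []
    for strand, base_ref, num_col, den_col in (
        (TOP, _CODE_C, _CODE_T, _CODE_C),
        (BOTTOM, _CODE_G, _CODE_A, _CODE_G),
    ):
        at = np.where(ref_codes == base_ref)[0]
        c = counts.counts[strand][at]
        n_conv = c[:, num_col]
        depth = c[:, num_col] + c[:, den_col]
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(depth >= max(min_depth, 1), 100.0 * n_conv / depth, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "pos": at + 1,
                    "strand": strand,
                    "n_converted": n_conv,
                    "depth": depth,
                    "rate_pct": rate,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True).sort_values(
        ["pos", "strand"], ignore_index=True
    )
    return ConversionProfile(table, min_depth)


DEFAULT_PROFILE_COLUMNS = {
    "pos": "pos",
    "strand": "strand",
    "rate_pct": "rate_pct",
    "depth": "depth",
}


def read_conversion_table(
    path,
    column_map: dict[str, str] | None = None,
    min_depth: int = 10,
) -> ConversionProfile:
    """Read a per-base conversion-rate TSV into a :class:`ConversionProfile`.

    ``column_map`` maps the canonical names (pos, strand, rate_pct, depth) to
    the file's headers, so externally produced per-base tables (e.g. a
    supplementary per-cytosine conversion listing) load without editing.
    Converted counts are reconstructed from rate and depth.
    """
    cmap = {**DEFAULT_PROFILE_COLUMNS, **(column_map or {})}
    df = pd.read_csv(path, sep="\t")
    missing = [v for v in cmap.values() if v not in df.columns]
    if missing:
        raise ValueError(f"conversion table missing columns {missing}")
    out = pd.DataFrame(
        {
            "pos": df[cmap["pos"]].astype(int),
            "strand": df[cmap["strand"]].astype(str),
            "depth": df[cmap["depth"]].astype(int),
            "rate_pct": pd.to_numeric(df[cmap["rate_pct"]], errors="coerce"),
        }
    )
    out["n_converted"] = (
        (out["rate_pct"].fillna(0.0) * out["depth"] / 100.0).round().astype(int)
    )
    out.loc[out["depth"] < min_depth, "rate_pct"] = np.nan
    out = out[["pos", "strand", "n_converted", "depth", "rate_pct"]]
    return ConversionProfile(out.sort_values(["pos", "strand"], ignore_index=True), min_depth)


def alignments_to_tsv(alignments: Sequence[BisulfiteAlignment]) -> str:
    rows = ["read_id\tref_start\tstrand\trc\tn_mismatch\tambiguous\tcigar"]
    for a in alignments:
        cig = "".join(f"{n}{op}" for op, n in a.edit_ops)
        rows.append(
            f"{a.read_id}\t{a.ref_start}\t{a.mapped_strand}\t{int(a.reverse_complemented)}"
            f"\t{a.n_mismatch}\t{int(a.ambiguity_flag)}\t{cig}"
        )
    return "\n".join(rows) + "\n"
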
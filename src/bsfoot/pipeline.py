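"""End-to-end pipeline: simulate -> align -> filter -> count -> profile -> boundary.

One top-level seed fans out to per-stage seeds (seed + stage index) so every
stage is independently reproducible; a JSON manifest records all parameters
and derived seeds.  All outputs are plain-text TSV/FASTA/FASTQ/JSON and are
byte-identical under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .boundary import detect_boundary, regime_summary
from .bsmap import (
    align_bisulfite_reads,
    alignments_to_tsv,
    conversion_profile,
    count_bases,
    filter_alignments,
)
from .seqcore import write_fasta
from .synthetic import (
    ExposureModel,
    ReadSimConfig,
    reads_to_fastq,
    simulate_bisulfite_reads,
    simulate_ty1_like_reference,
)

_STAGE_SEEDS = {"reference": 0, "reads": 1, "boundary_test": 2}


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`."""

    # reference
    ref_length: int = 2000
    ir_arm: int = 15
    ir_loop: int = 9
    ir_position: int = 1011
    gc_content: float = 0.40
    # exposure model
    boundary_pos: int = 1011
    p_up: float = 0.20
    p_down: float = 0.04
    conv_eff: float = 1.0
    seq_error: float = 0.0
    correlation_mode: str = "per_base"
    # reads
    n_reads: int = 20000
    read_length: int = 250
    strand_fraction_top: float = 0.5
    # mapping
    max_mismatch_frac: float = 0.1
    gapped: bool = False
    min_depth: int = 10
    # boundary
    search_start: int | None = None
    search_end: int | None = None
    p_value_method: str = "permutation"
    n_permutations: int = 199
    # run
    seed: int = 0

    def validate(self) -> None:
        checks = [
            (self.ref_length > 0, "ref_length must be > 0"),
            (self.ir_arm >= 4, "ir_arm must be >= 4"),
            (self.ir_loop >= 3, "ir_loop must be >= 3"),
            (1 <= self.ir_position <= self.ref_length, "ir_position outside reference"),
            (1 <= self.boundary_pos <= self.ref_length, "boundary_pos outside reference"),
            (0 <= self.p_up <= 1, "p_up must be in [0,1]"),
            (0 <= self.p_down <= 1, "p_down must be in [0,1]"),
            (0 <= self.conv_eff <= 1, "conv_eff must be in [0,1]"),
            (0 <= self.seq_error <= 1, "seq_error must be in [0,1]"),
            (self.correlation_mode in {"per_base", "per_molecule_segment"},
             "unknown correlation_mode"),
            (self.n_reads > 0, "n_reads must be > 0"),
            (0 < self.read_length <= self.ref_length,
             "read_length must be in (0, ref_length]"),
            (0 <= self.strand_fraction_top <= 1, "strand_fraction_top must be in [0,1]"),
            (0 <= self.max_mismatch_frac < 1, "max_mismatch_frac must be in [0,1)"),
            (self.min_depth >= 1, "min_depth must be >= 1"),
            (self.p_value_method in {"permutation", "chi2"}, "unknown p_value_method"),
            (self.n_permutations >= 1, "n_permutations must be >= 1"),
            (self.seed >= 0, "seed must be >= 0"),
        ]
        errors = [msg for ok, msg in checks if not ok]
        if errors:
            raise ValueError("invalid pipeline config: " + "; ".join(errors))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def stage_seed(self, stage: str) -> int:
        return (self.seed + _STAGE_SEEDS[stage]) % (2**31)


@dataclass
class PipelineResult:
    reference: object
    ir: object
    truth: object
    boundary: object
    regimes: object
    n_reads_aligned: int
    n_reads_filtered: int
    profile: object


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run the synthetic-to-report pipeline; optionally write every stage output."""
    config.validate()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    ref, ir = simulate_ty1_like_reference(
        config.ref_length,
        {"arm": config.ir_arm, "loop": config.ir_loop, "position": config.ir_position},
        gc_content=config.gc_content,
        seed=config.stage_seed("reference"),
    )
    model = ExposureModel(
        boundary_pos=config.boundary_pos,
        p_up=config.p_up,
        p_down=config.p_down,
        conv_eff=config.conv_eff,
        seq_error=config.seq_error,
        correlation_mode=config.correlation_mode,
    )
    sim_cfg = ReadSimConfig(
        n_reads=config.n_reads,
        read_length=config.read_length,
        strand_fraction_top=config.strand_fraction_top,
        seed=config.stage_seed("reads"),
    )
    reads, truth = simulate_bisulfite_reads(ref, model, sim_cfg)

    alignments = align_bisulfite_reads(
        reads, ref, max_mismatch_frac=config.max_mismatch_frac, gapped=config.gapped
    )
    kept = filter_alignments(alignments)
    counts = count_bases(kept, ref)
    profile = conversion_profile(counts, ref, min_depth=config.min_depth)

    search = None
    if config.search_start is not None and config.search_end is not None:
        search = (config.search_start, config.search_end)
    call = detect_boundary(
        profile,
        search_interval=search,
        method=config.p_value_method,
        n_permutations=config.n_permutations,
        seed=config.stage_seed("boundary_test"),
    )
    regimes = regime_summary(profile, call.position)

    if out is not None:
        write_fasta([ref], out / "reference.fasta")
        reads_to_fastq(reads, out / "reads.fastq")
        (out / "truth_reads.tsv").write_text(truth.to_read_tsv())
        (out / "truth_positions.tsv").write_text(truth.to_position_tsv())
        (out / "alignments.tsv").write_text(alignments_to_tsv(alignments))
        (out / "counts.tsv").write_text(counts.to_tsv())
        (out / "profile.tsv").write_text(profile.to_tsv())
        (out / "boundary.json").write_text(json.dumps(call.to_dict(), indent=2) + "\n")
        (out / "regimes.tsv").write_text(_regimes_tsv(regimes))
        manifest = {
            "tool": "bsfoot",
            "version": __version__,
            "config": asdict(config),
            "stage_seeds": {s: config.stage_seed(s) for s in _STAGE_SEEDS},
            "planted_ir": {
                "left_arm": [ir.left_arm.start, ir.left_arm.end],
                "right_arm": [ir.right_arm.start, ir.right_arm.end],
                "loop": [ir.loop.start, ir.loop.end],
            },
            "n_reads_aligned": len(alignments),
            "n_reads_filtered": len(kept),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    return PipelineResult(
        reference=ref,
        ir=ir,
        truth=truth,
        boundary=call,
        regimes=regimes,
        n_reads_aligned=len(alignments),
        n_reads_filtered=len(kept),
        profile=profile,
    )


def _regimes_tsv(r) -> str:
    rows = ["metric\tvalue"]
    for k in (
        "upstream_max",
        "upstream_mean",
        "downstream_min",
        "downstream_mean",
        "n_upstream",
        "n_downstream",
    ):
        rows.append(f"{k}\t{getattr(r, k):.6g}")
    return "\n".join(rows) + "\n"
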
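"""Synthetic genomes, TSS tables, pentamer tables, tracks and variant sets.

The generator produces everything the pipeline consumes, with a plantable
class signal: functional variants are enriched for A/T -> G/C substitutions
(probability ``p_gc_gain``), and the synthetic pentamer table trends
monotonically with pentamer GC count, so a GC-gaining substitution also
shifts the local shape profile.  Neutral variants draw (ref, alt) uniformly
over the 12 ordered unequal base pairs.  Everything is deterministic given
the bundle seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._seq import BASES, revcomp
from .errors import CapacityError, ConfigurationError, ContractError
from .features import AnnotationLayout, Pwm, ZScoreModel, read_pwms, write_pwms
from .shape import (
    PentamerTable,
    all_pentamers,
    load_pentamer_table,
    pentamer_index,
    write_pentamer_table,
)
from .variants import (
    AnnotationTrack,
    TssEntry,
    VariantRecord,
    read_bed_track,
    read_tss_table,
    read_variants,
    write_bed_track,
    write_tss_table,
    write_variants,
)

logger = logging.getLogger(__name__)

PROMOTER_SPAN = 5000
DEFAULT_SEED = 20181129

# uniform value ranges per pentamer-table column (units: Å for MGW, degrees
# for the rest); sign says whether the value trends up (+1) or down (-1)
# with pentamer GC count
_SHAPE_RANGES: dict[str, tuple[float, float, int]] = {
    "mgw": (3.0, 7.0, -1),  # GC-rich pentamers -> narrower minor groove
    "prot": (-18.0, 0.0, +1),  # GC-rich -> larger (less negative) ProT
    "roll": (-8.0, 8.0, +1),
    "helt": (30.0, 40.0, +1),
}


@dataclass
class SignalConfig:
    """Study conditions of the synthetic benchmark."""

    n_pos: int = 400
    n_neg: int = 800
    p_gc_gain: float = 0.8
    neg_uniform: bool = True
    gc_context: float = 0.5
    n_chrom: int = 22
    chrom_len: int = 12000
    coverage: float = 0.3
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ContractError("variant counts must be >= 1")
        if not 0 <= self.p_gc_gain <= 1:
            raise ContractError("p_gc_gain must lie in [0, 1]")
        if not 0 < self.gc_context < 1:
            raise ContractError("gc_context must lie in (0, 1)")
        if not 0 <= self.coverage <= 1:
            raise ContractError("coverage must lie in [0, 1]")
        if not self.neg_uniform:
            raise ConfigurationError(
                "only the uniform negative allele model is implemented"
            )


@dataclass
class SyntheticBundle:
    """All inputs of one synthetic experiment plus its manifest."""

    genome: dict[str, str]
    tss: list[TssEntry]
    variants: list[VariantRecord]
    pentamers: PentamerTable
    tracks: dict[str, AnnotationTrack]
    layout: AnnotationLayout
    pwms: tuple[Pwm, ...]
    background: tuple[float, float, float, float]
    zmodel: ZScoreModel
    manifest: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# pentamer table
# ---------------------------------------------------------------------------


def _banded_value(lo: float, hi: float, sign: int, gc: int, u: float) -> float:
    """Value in the gc-count band of [lo, hi]; strictly monotone in gc."""
    width = (hi - lo) / 6.0
    band = gc if sign > 0 else 5 - gc
    return lo + band * width + u * width


def make_pentamer_table(seed: int = DEFAULT_SEED, symmetric: bool = True) -> PentamerTable:
    """Random complete pentamer table with a deterministic GC trend.

    Each column is drawn uniformly inside a band determined by the
    pentamer's GC count, so every shape value depends strictly
    monotonically on GC content.  When ``symmetric`` the reverse-complement
    identities are enforced by generating one canonical representative per
    pentamer pair.
    """
    rng = np.random.default_rng(seed)
    values = np.empty((1024, 6))
    done = np.zeros(1024, dtype=bool)
    for pent in all_pentamers():
        idx = pentamer_index(pent)
        if done[idx]:
            continue
        gc = sum(1 for c in pent if c in "GC")
        u = rng.random(6)
        row = np.array(
            [
                _banded_value(*_SHAPE_RANGES["mgw"], gc, u[0]),
                _banded_value(*_SHAPE_RANGES["prot"], gc, u[1]),
                _banded_value(*_SHAPE_RANGES["roll"], gc, u[2]),
                _banded_value(*_SHAPE_RANGES["roll"], gc, u[3]),
                _banded_value(*_SHAPE_RANGES["helt"], gc, u[4]),
                _banded_value(*_SHAPE_RANGES["helt"], gc, u[5]),
            ]
        )
        values[idx] = row
        done[idx] = True
        if symmetric:
            rc_idx = pentamer_index(revcomp(pent))
            # mgw/prot shared; left/right step roles swap under revcomp
            values[rc_idx] = row[[0, 1, 3, 2, 5, 4]]
            done[rc_idx] = True
    return PentamerTable(values, symmetric=symmetric)


# ---------------------------------------------------------------------------
# genome / TSS
# ---------------------------------------------------------------------------


def make_genome_and_tss(
    config: SignalConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[TssEntry]]:
    """I.i.d.-base contigs (GC fraction ``gc_context``) with one TSS each.

    Each TSS is placed so that the full 5 kb upstream promoter window plus
    the 7-nt shape flank fits inside the contig; strand alternates.
    """
    if config.chrom_len < 12000:
        raise ContractError("chrom_len must be >= 12000")
    rng = rng or np.random.default_rng(config.seed)
    p = np.array(
        [
            (1 - config.gc_context) / 2,
            config.gc_context / 2,
            config.gc_context / 2,
            (1 - config.gc_context) / 2,
        ]
    )
    genome: dict[str, str] = {}
    tss: list[TssEntry] = []
    base_arr = np.array(list(BASES))
    for i in range(config.n_chrom):
        chrom = f"chr{i + 1}"
        seq = "".join(base_arr[rng.choice(4, size=config.chrom_len, p=p)])
        genome[chrom] = seq
        strand = "+" if i % 2 == 0 else "-"
        jitter = int(rng.integers(0, 200))
        if strand == "+":
            tss_pos = PROMOTER_SPAN + 100 + jitter  # upstream window >= pos 108
        else:
            tss_pos = config.chrom_len - PROMOTER_SPAN - 100 - jitter
        tss.append(TssEntry(chrom, tss_pos, strand, f"gene{i + 1}"))
    return genome, tss


def _promoter_positions(entry: TssEntry) -> range:
    """1-based positions of the 5 kb window immediately upstream of a TSS."""
    if entry.strand == "+":
        return range(entry.tss_pos - PROMOTER_SPAN, entry.tss_pos)
    return range(entry.tss_pos + 1, entry.tss_pos + PROMOTER_SPAN + 1)


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

_GC_GAIN_PAIRS = tuple((r, a) for r in "AT" for a in "GC")
_ALL_PAIRS = tuple((r, a) for r in BASES for a in BASES if r != a)


def make_variant_set(
    genome: dict[str, str],
    tss: list[TssEntry],
    signal: SignalConfig,
    rng: np.random.Generator | None = None,
) -> list[VariantRecord]:
    """Labeled SNVs inside promoter windows with the planted allele signal.

    Positives: with probability ``p_gc_gain`` the (ref, alt) pair is drawn
    from the A/T -> G/C pairs; otherwise, and for all negatives, uniformly
    from the 12 ordered unequal pairs.  A site matching the drawn ref base
    is sampled (resampling until the ref class matches); positions are
    never reused.  Negatives carry MAF ~ U(0.01, 0.5) (common variants),
    positives carry no MAF.
    """
    rng = rng or np.random.default_rng(signal.seed)
    candidates = [(e.chrom, pos) for e in tss for pos in _promoter_positions(e)]
    n_total = signal.n_pos + signal.n_neg
    if n_total > len(candidates):
        raise CapacityError(
            f"requested {n_total} variants but only {len(candidates)} promoter positions"
        )
    used: set[tuple[str, int]] = set()
    variants: list[VariantRecord] = []
    max_attempts = 200 * n_total + 10000

    def draw_site(ref: str) -> tuple[str, int]:
        attempts = 0
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise CapacityError(
                    f"could not place a variant with ref {ref!r}: space exhausted"
                )
            chrom, pos = candidates[rng.integers(len(candidates))]
            if (chrom, pos) in used:
                continue
            if genome[chrom][pos - 1] == ref:
                used.add((chrom, pos))
                return chrom, pos

    for _ in range(signal.n_pos):
        if rng.random() < signal.p_gc_gain:
            ref, alt = _GC_GAIN_PAIRS[rng.integers(len(_GC_GAIN_PAIRS))]
        else:
            ref, alt = _ALL_PAIRS[rng.integers(len(_ALL_PAIRS))]
        chrom, pos = draw_site(ref)
        variants.append(VariantRecord(chrom, pos, ref, alt, label="functional"))
    for _ in range(signal.n_neg):
        ref, alt = _ALL_PAIRS[rng.integers(len(_ALL_PAIRS))]
        chrom, pos = draw_site(ref)
        variants.append(
            VariantRecord(
                chrom,
                pos,
                ref,
                alt,
                label="neutral",
                maf=float(rng.uniform(0.01, 0.5)),
            )
        )
    return variants


# ---------------------------------------------------------------------------
# tracks / PWMs
# ---------------------------------------------------------------------------


def make_tracks(
    genome: dict[str, str],
    tss: list[TssEntry],
    layout: AnnotationLayout | None = None,
    coverage: float = 0.3,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> dict[str, AnnotationTrack]:
    """Binary tracks covering ``coverage`` of each promoter + scored tracks.

    Each binary track places exactly one interval per promoter window whose
    length is ``coverage`` of the window (so coverage 0 -> empty tracks and
    coverage 1 -> saturation).  GERP-like and PhastCons-like tracks tile
    promoters with 100-bp scored intervals.
    """
    layout = layout or AnnotationLayout()
    rng = rng or np.random.default_rng(DEFAULT_SEED if seed is None else seed)
    tracks: dict[str, AnnotationTrack] = {}
    windows = []
    for e in tss:
        pos = _promoter_positions(e)
        windows.append((e.chrom, pos.start - 1, pos.stop - 1))  # 0-based half-open

    for tid in layout.binary_track_ids():
        intervals = []
        if coverage > 0:
            for chrom, start, end in windows:
                ilen = max(1, round(coverage * (end - start)))
                offset = int(rng.integers(0, end - start - ilen + 1)) if ilen < end - start else 0
                intervals.append((chrom, start + offset, start + offset + ilen, 1.0))
        tracks[tid] = AnnotationTrack(tid, intervals, kind="binary")

    for tid, lo, hi in (
        (layout.gerp_id, -2.0, 4.0),
        (layout.phastcons_id, 0.0, 1.0),
    ):
        intervals = []
        for chrom, start, end in windows:
            for tile_start in range(start, end, 100):
                tile_end = min(tile_start + 100, end)
                intervals.append(
                    (chrom, tile_start, tile_end, float(rng.uniform(lo, hi)))
                )
        tracks[tid] = AnnotationTrack(tid, intervals, kind="scored")
    return tracks


def make_pwms(
    layout: AnnotationLayout | None = None,
    width: int = 8,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[Pwm, ...]:
    """One random PWM per TF (Dirichlet positions, floored at 0.02)."""
    layout = layout or AnnotationLayout()
    rng = rng or np.random.default_rng(DEFAULT_SEED if seed is None else seed)
    pwms = []
    for tf in layout.tfs:
        probs = []
        for _ in range(width):
            p = rng.dirichlet(np.full(4, 0.5))
            p = np.maximum(p, 0.02)
            p = p / p.sum()
            probs.append(tuple(p))
        pwms.append(Pwm(tf, tuple(probs)))
    return tuple(pwms)


# ---------------------------------------------------------------------------
# bundle orchestration and on-disk layout
# ---------------------------------------------------------------------------

# slightly AT-rich surrogate-Z background; a uniform background would be the
# degenerate (sigma^2 = 0) case
_Z_BACKGROUND = (0.29, 0.21, 0.21, 0.29)


def make_bundle(signal: SignalConfig | None = None) -> SyntheticBundle:
    """Generate a complete, self-consistent synthetic experiment."""
    signal = signal or SignalConfig()
    children = np.random.SeedSequence(signal.seed).spawn(5)
    rngs = [np.random.default_rng(c) for c in children]
    layout = AnnotationLayout()
    genome, tss = make_genome_and_tss(signal, rng=rngs[0])
    pentamers = make_pentamer_table(seed=int(children[1].generate_state(1)[0] % 2**31))
    variants = make_variant_set(genome, tss, signal, rng=rngs[2])
    tracks = make_tracks(genome, tss, layout, coverage=signal.coverage, rng=rngs[3])
    pwms = make_pwms(layout, rng=rngs[4])
    manifest = {"format": "promshape-bundle-v1", **asdict(signal)}
    return SyntheticBundle(
        genome=genome,
        tss=tss,
        variants=variants,
        pentamers=pentamers,
        tracks=tracks,
        layout=layout,
        pwms=pwms,
        background=(0.25, 0.25, 0.25, 0.25),
        zmodel=ZScoreModel(_Z_BACKGROUND),
        manifest=manifest,
    )


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA into a chromosome -> sequence mapping (via pyfaidx)."""
    import pyfaidx

    with pyfaidx.Fasta(str(path)) as fasta:
        return {name: str(fasta[name][:]).upper() for name in fasta.keys()}


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Write the bundle as a directory of plain-text artifacts."""
    outdir = Path(outdir)
    (outdir / "tracks").mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.genome, outdir / "genome.fa")
    write_tss_table(bundle.tss, outdir / "tss.tsv")
    write_variants(bundle.variants, outdir / "variants.tsv")
    write_pentamer_table(bundle.pentamers, outdir / "pentamers.tsv")
    for tid, track in bundle.tracks.items():
        safe = tid.replace(":", "_").replace("/", "_")
        write_bed_track(track, outdir / "tracks" / f"{safe}.bed")
    write_pwms(bundle.pwms, outdir / "pwms.tsv")
    manifest = dict(bundle.manifest)
    manifest["tracks"] = {
        tid: {"file": f"tracks/{tid.replace(':', '_').replace('/', '_')}.bed", "kind": t.kind}
        for tid, t in bundle.tracks.items()
    }
    manifest["z_background"] = list(bundle.zmodel.q)
    manifest["pwm_background"] = list(bundle.background)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def load_bundle(indir: str | Path) -> SyntheticBundle:
    """Load a bundle directory written by :func:`write_bundle`."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    layout = AnnotationLayout()
    tracks = {
        tid: read_bed_track(indir / meta["file"], tid, kind=meta["kind"])
        for tid, meta in manifest["tracks"].items()
    }
    signal_keys = {f.name for f in SignalConfig.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    signal_kwargs = {k: v for k, v in manifest.items() if k in signal_keys}
    return SyntheticBundle(
        genome=read_fasta(indir / "genome.fa"),
        tss=read_tss_table(indir / "tss.tsv"),
        variants=read_variants(indir / "variants.tsv", dialect="tsv"),
        pentamers=load_pentamer_table(indir / "pentamers.tsv", symmetric=False),
        tracks=tracks,
        layout=layout,
        pwms=tuple(read_pwms(indir / "pwms.tsv")),
        background=tuple(manifest.get("pwm_background", (0.25, 0.25, 0.25, 0.25))),
        zmodel=ZScoreModel(tuple(manifest.get("z_background", _Z_BACKGROUND))),
        manifest={k: v for k, v in manifest.items() if k not in ("tracks",)},
    )
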
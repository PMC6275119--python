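"""The ten feature groups and feature-matrix assembly.

Group sizes (fixed by the schema):

====================  ====  =========================================================
group                 size  content
====================  ====  =========================================================
sequence                52  9-nt one-hot (36) + alt-allele one-hot (4) + 12 mutation-
                            type indicators
gc                       8  GC fraction of the 7- and 9-nt centered windows for the
                            reference and mutated sequence, their difference and its
                            absolute value
shape                   88  MGW/ProT/Roll/HelT mutated values and mut-ref differences
                            at SNV offsets -5..+5 (see :mod:`promshape.shape`)
dinucleotide            16  observed - expected frequency of each ordered dinucleotide
                            in the reference 9-mer
histone                 38  per-(mark, cell line) overlap binaries (2 x 16) + per-mark
                            and either-mark cell-line means + any-cell binaries
tfbs                    12  per-TF overlap binaries (10) + mean + any
tf_disruption            1  empirical p-value that the mutation disrupts the strongest
                            PWM hit
tf_maxscore              1  maximum PWM log-odds hit over ref and mut windows
dnase                    1  DNase hypersensitivity overlap binary
conservation            10  GERP/PhastCons site scores and 9-nt means + surrogate
                            background-log-likelihood Z for windows 7 and 9 (ref, mut,
                            diff)
====================  ====  =========================================================
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import BASES, MUTATION_TYPES, gc_fraction, revcomp
from .errors import (
    ConfigurationError,
    ContractError,
    PromshapeError,
    SchemaError,
)
from .shape import (
    SHAPE_WINDOW_FLANK,
    PentamerTable,
    shape_feature_names,
    shape_feature_vector,
)
from .variants import (
    AnnotationTrack,
    SequenceWindow,
    VariantRecord,
    fetch_window,
    substitute_center,
)

logger = logging.getLogger(__name__)

GROUP_ORDER = (
    "sequence",
    "gc",
    "shape",
    "dinucleotide",
    "histone",
    "tfbs",
    "tf_disruption",
    "tf_maxscore",
    "dnase",
    "conservation",
)

GROUP_SIZES = {
    "sequence": 52,
    "gc": 8,
    "shape": 88,
    "dinucleotide": 16,
    "histone": 38,
    "tfbs": 12,
    "tf_disruption": 1,
    "tf_maxscore": 1,
    "dnase": 1,
    "conservation": 10,
}

DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)


# ---------------------------------------------------------------------------
# schema
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationLayout:
    """Declares which annotation tracks exist and how they are named."""

    cell_lines: tuple[str, ...] = (
        "GM12878",
        "K562",
        "HepG2",
        "HeLa-S3",
        "HUVEC",
        "H1-hESC",
        "A549",
        "MCF-7",
        "IMR90",
        "SK-N-SH",
        "HCT116",
        "NHEK",
        "HSMM",
        "NHLF",
        "HMEC",
        "AG04450",
    )
    marks: tuple[str, ...] = ("H3K9ac", "H3K4me3")
    tfs: tuple[str, ...] = (
        "CTCF",
        "POLR2A",
        "SP1",
        "MYC",
        "MAX",
        "JUN",
        "FOS",
        "EGR1",
        "YY1",
        "NRF1",
    )
    dnase_id: str = "DNase"
    gerp_id: str = "GERP"
    phastcons_id: str = "PhastCons"

    def __post_init__(self) -> None:
        if len(self.cell_lines) != 16 or len(self.marks) != 2 or len(self.tfs) != 10:
            raise ConfigurationError(
                "layout must declare 16 cell lines x 2 marks and 10 TFs"
            )

    def histone_track_id(self, mark: str, cell: str) -> str:
        return f"{mark}:{cell}"

    def tf_track_id(self, tf: str) -> str:
        return f"TF:{tf}"

    def binary_track_ids(self) -> list[str]:
        ids = [
            self.histone_track_id(m, c) for m in self.marks for c in self.cell_lines
        ]
        ids += [self.tf_track_id(t) for t in self.tfs]
        ids.append(self.dnase_id)
        return ids


def _sequence_names() -> list[str]:
    names = [f"seq_pos{p}_{b}" for p in range(1, 10) for b in BASES]
    names += [f"seq_alt_{b}" for b in BASES]
    names += [f"seq_mut_{r}to{a}" for r, a in MUTATION_TYPES]
    return names


def _gc_names() -> list[str]:
    return [
        f"gc_{what}{w}" for w in (7, 9) for what in ("ref", "mut", "diff", "absdiff")
    ]


def _dinucleotide_names() -> list[str]:
    return [f"dinuc_{d}" for d in DINUCLEOTIDES]


def _histone_names(layout: AnnotationLayout) -> list[str]:
    names = [f"hist_{m}_{c}" for m in layout.marks for c in layout.cell_lines]
    names += [f"hist_mean_{m}" for m in layout.marks] + ["hist_mean_either"]
    names += [f"hist_any_{m}" for m in layout.marks] + ["hist_any_either"]
    return names


def _tfbs_names(layout: AnnotationLayout) -> list[str]:
    return [f"tfbs_{t}" for t in layout.tfs] + ["tfbs_mean", "tfbs_any"]


def _conservation_names() -> list[str]:
    return [
        "gerp_site",
        "gerp_mean9",
        "phastcons_site",
        "phastcons_mean9",
        "z_ref7",
        "z_mut7",
        "z_diff7",
        "z_ref9",
        "z_mut9",
        "z_diff9",
    ]


def group_feature_names(group: str, layout: AnnotationLayout | None = None) -> list[str]:
    """Canonical column names of one feature group."""
    layout = layout or AnnotationLayout()
    table = {
        "sequence": _sequence_names,
        "gc": _gc_names,
        "shape": shape_feature_names,
        "dinucleotide": _dinucleotide_names,
        "histone": lambda: _histone_names(layout),
        "tfbs": lambda: _tfbs_names(layout),
        "tf_disruption": lambda: ["tf_disruption_pval"],
        "tf_maxscore": lambda: ["tf_max_logodds"],
        "dnase": lambda: ["dnase"],
        "conservation": _conservation_names,
    }
    if group not in table:
        raise ConfigurationError(f"unknown feature group {group!r}")
    return table[group]()


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered (column name, group tag) pairs with enforced group sizes."""

    columns: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.columns]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate column names in schema")
        sizes: dict[str, int] = {}
        for _, g in self.columns:
            sizes[g] = sizes.get(g, 0) + 1
        for g, n in sizes.items():
            if GROUP_SIZES.get(g) != n:
                raise ConfigurationError(
                    f"group {g!r} has {n} columns, expected {GROUP_SIZES.get(g)}"
                )

    @classmethod
    def canonical(
        cls,
        groups: Sequence[str] = GROUP_ORDER,
        layout: AnnotationLayout | None = None,
    ) -> "FeatureSchema":
        """Schema for the given groups in canonical order."""
        unknown = set(groups) - set(GROUP_ORDER)
        if unknown:
            raise ConfigurationError(f"unknown feature groups {sorted(unknown)}")
        if not groups:
            raise ConfigurationError("no feature groups selected")
        cols = []
        for g in GROUP_ORDER:
            if g in groups:
                cols += [(name, g) for name in group_feature_names(g, layout)]
        return cls(tuple(cols))

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.columns]

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for _, g in self.columns:
            if g not in seen:
                seen.append(g)
        return seen

    def group_columns(self, group: str) -> list[str]:
        cols = [n for n, g in self.columns if g == group]
        if not cols:
            raise ConfigurationError(f"group {group!r} not in schema")
        return cols

    def __len__(self) -> int:
        return len(self.columns)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.columns, columns=["name", "group"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureSchema":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(tuple(zip(df["name"], df["group"])))


# ---------------------------------------------------------------------------
# per-group extractors
# ---------------------------------------------------------------------------


def encode_sequence(ref9: str, alt: str) -> np.ndarray:
    """52 sequence features: one-hot 9-mer, one-hot alt, mutation-type bits."""
    if len(ref9) != 9 or any(c not in BASES for c in ref9):
        raise ContractError("ref9 must be a 9-mer over ACGT")
    if alt not in BASES or alt == ref9[4]:
        raise ContractError("alt must be a base differing from the 9-mer center")
    out = np.zeros(52)
    for p, base in enumerate(ref9):
        out[4 * p + BASES.index(base)] = 1.0
    out[36 + BASES.index(alt)] = 1.0
    out[40 + MUTATION_TYPES.index((ref9[4], alt))] = 1.0
    return out


def gc_features(ref_window: SequenceWindow | str, mut_window: SequenceWindow | str) -> np.ndarray:
    """8 GC features over the centered 7- and 9-nt windows."""
    ref = ref_window if isinstance(ref_window, str) else ref_window.seq
    mut = mut_window if isinstance(mut_window, str) else mut_window.seq
    if len(ref) != len(mut) or len(ref) < 9 or len(ref) % 2 == 0:
        raise ContractError("windows must be equal odd length >= 9")
    mid = len(ref) // 2
    out = np.empty(8)
    for k, w in enumerate((7, 9)):
        f = w // 2
        gr = gc_fraction(ref[mid - f : mid + f + 1])
        gm = gc_fraction(mut[mid - f : mid + f + 1])
        out[4 * k : 4 * k + 4] = (gr, gm, gm - gr, abs(gm - gr))
    return out


def dinucleotide_features(ref9: str) -> np.ndarray:
    """16 observed-minus-expected ordered-dinucleotide frequencies of the 9-mer."""
    if len(ref9) != 9 or any(c not in BASES for c in ref9):
        raise ContractError("ref9 must be a 9-mer over ACGT")
    mono = {b: ref9.count(b) / 9 for b in BASES}
    obs = {d: 0.0 for d in DINUCLEOTIDES}
    for i in range(8):
        obs[ref9[i : i + 2]] += 1 / 8
    return np.array([obs[d] - mono[d[0]] * mono[d[1]] for d in DINUCLEOTIDES])


def annotation_features(
    variant: VariantRecord,
    tracks: Mapping[str, AnnotationTrack],
    layout: AnnotationLayout,
) -> np.ndarray:
    """38 histone + 12 TFBS + 1 DNase binary-overlap features."""
    absent = [t for t in layout.binary_track_ids() if t not in tracks]
    if absent:
        raise ConfigurationError(f"missing annotation tracks: {absent}")

    per_mark: dict[str, np.ndarray] = {}
    for mark in layout.marks:
        per_mark[mark] = np.array(
            [
                float(tracks[layout.histone_track_id(mark, c)].overlaps(variant.chrom, variant.pos))
                for c in layout.cell_lines
            ]
        )
    either = np.maximum(*per_mark.values())  # per-cell OR across marks
    hist = np.concatenate(
        [
            *per_mark.values(),
            [m.mean() for m in per_mark.values()] + [either.mean()],
            [float(m.any()) for m in per_mark.values()] + [float(either.any())],
        ]
    )

    tf_bits = np.array(
        [
            float(tracks[layout.tf_track_id(t)].overlaps(variant.chrom, variant.pos))
            for t in layout.tfs
        ]
    )
    tfbs = np.concatenate([tf_bits, [tf_bits.mean(), float(tf_bits.any())]])
    dnase = np.array([float(tracks[layout.dnase_id].overlaps(variant.chrom, variant.pos))])
    return np.concatenate([hist, tfbs, dnase])


@dataclass(frozen=True)
class ZScoreModel:
    """Background-composition log-likelihood standardization.

    For i.i.d. background base probabilities q, the per-base log-likelihood
    has mean mu1 = sum_b q_b log q_b and variance
    sigma1_sq = sum_b q_b (log q_b)^2 - mu1^2, so a window s of length w
    scores Z(s) = (sum_i log q_{s_i} - w mu1) / sqrt(w sigma1_sq).
    """

    q: tuple[float, float, float, float]  # A, C, G, T

    def __post_init__(self) -> None:
        arr = np.asarray(self.q, float)
        if arr.shape != (4,) or (arr <= 0).any() or abs(arr.sum() - 1.0) > 1e-9:
            raise ConfigurationError("background q must be 4 positive values summing to 1")

    @property
    def mu1(self) -> float:
        q = np.asarray(self.q)
        return float(np.sum(q * np.log(q)))

    @property
    def sigma1_sq(self) -> float:
        q = np.asarray(self.q)
        return float(np.sum(q * np.log(q) ** 2) - self.mu1**2)

    def z(self, seq: str) -> float:
        if self.sigma1_sq <= 1e-12:
            raise ConfigurationError(
                "degenerate background (all bases equally likely): Z undefined"
            )
        logq = {b: math.log(self.q[i]) for i, b in enumerate(BASES)}
        total = sum(logq[c] for c in seq)
        w = len(seq)
        return (total - w * self.mu1) / math.sqrt(w * self.sigma1_sq)


def conservation_features(
    variant: VariantRecord,
    gerp_track: AnnotationTrack,
    phastcons_track: AnnotationTrack,
    zmodel: ZScoreModel,
    ref_win: SequenceWindow,
    mut_win: SequenceWindow,
) -> np.ndarray:
    """10 conservation features: site/window track scores + surrogate Z-scores."""
    if zmodel.sigma1_sq <= 1e-12:
        raise ConfigurationError("degenerate Z-score background (sigma^2 = 0)")
    chrom, pos = variant.chrom, variant.pos
    gerp_site = gerp_track.value_at(chrom, pos)
    gerp_mean9 = float(
        np.mean([gerp_track.value_at(chrom, p) for p in range(pos - 4, pos + 5)])
    )
    pc_site = phastcons_track.value_at(chrom, pos)
    pc_mean9 = float(
        np.mean([phastcons_track.value_at(chrom, p) for p in range(pos - 4, pos + 5)])
    )
    out = [gerp_site, gerp_mean9, pc_site, pc_mean9]
    for w in (7, 9):
        f = w // 2
        zr = zmodel.z(ref_win.subwindow(f))
        zm = zmodel.z(mut_win.subwindow(f))
        out += [zr, zm, zm - zr]
    return np.array(out)


# ---------------------------------------------------------------------------
# PWM features
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Pwm:
    """Position weight matrix (probabilities, pseudocount already applied)."""

    name: str
    probs: tuple[tuple[float, float, float, float], ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.probs, float)
        if arr.ndim != 2 or arr.shape[1] != 4 or (arr <= 0).any():
            raise ConfigurationError(f"PWM {self.name}: probabilities must be positive")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-6):
            raise ConfigurationError(f"PWM {self.name}: rows must sum to 1")

    @property
    def width(self) -> int:
        return len(self.probs)

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.probs, float)


def best_logodds(window: str, pwm: Pwm, background: Sequence[float]) -> float:
    """Best log-odds hit of one PWM over all offsets and both strands."""
    bg = np.asarray(background, float)
    if bg.shape != (4,) or (bg <= 0).any():
        raise ConfigurationError("background must be 4 positive frequencies")
    logodds = np.log(pwm.matrix / bg)
    best = -math.inf
    for seq in (window, revcomp(window)):
        idx = [BASES.index(c) for c in seq]
        for off in range(len(seq) - pwm.width + 1):
            score = sum(logodds[j, idx[off + j]] for j in range(pwm.width))
            best = max(best, score)
    if best == -math.inf:
        raise ContractError(f"window shorter than PWM {pwm.name}")
    return best


def tf_motif_features(
    ref_win: SequenceWindow | str,
    mut_win: SequenceWindow | str,
    pwms: Sequence[Pwm],
    background: Sequence[float],
    n_null: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """(disruption p-value, maximum log-odds hit) for one SNV.

    The disruption statistic is delta = best_ref - best_mut for the PWM with
    the strongest reference hit; its empirical null redraws the center base
    uniformly among the three alternatives, with add-one smoothing:
    p = (1 + #{delta_null >= delta_obs}) / (n_null + 1).
    """
    if not pwms:
        raise ConfigurationError("empty PWM set")
    ref = ref_win if isinstance(ref_win, str) else ref_win.seq
    mut = mut_win if isinstance(mut_win, str) else mut_win.seq
    mid = len(ref) // 2

    best_ref, best_pwm = -math.inf, None
    feature_max = -math.inf
    for pwm in pwms:
        br = best_logodds(ref, pwm, background)
        bm = best_logodds(mut, pwm, background)
        feature_max = max(feature_max, br, bm)
        if br > best_ref:
            best_ref, best_pwm = br, pwm
    assert best_pwm is not None
    best_mut = best_logodds(mut, best_pwm, background)
    delta_obs = best_ref - best_mut

    rng = np.random.default_rng(seed)
    alternatives = [b for b in BASES if b != ref[mid]]
    exceed = 0
    for _ in range(n_null):
        alt = alternatives[rng.integers(len(alternatives))]
        null_win = ref[:mid] + alt + ref[mid + 1 :]
        delta_null = best_ref - best_logodds(null_win, best_pwm, background)
        if delta_null >= delta_obs:
            exceed += 1
    pval = (1 + exceed) / (n_null + 1)
    return pval, feature_max


def write_pwms(pwms: Sequence[Pwm], path: str | Path) -> None:
    """Minimal tab format: name, position, p_A, p_C, p_G, p_T."""
    with open(path, "w") as fh:
        fh.write("name\tposition\tA\tC\tG\tT\n")
        for pwm in pwms:
            for i, row in enumerate(pwm.probs, start=1):
                fh.write(
                    pwm.name + f"\t{i}\t" + "\t".join(repr(float(v)) for v in row) + "\n"
                )


def read_pwms(path: str | Path) -> list[Pwm]:
    df = pd.read_csv(path, sep="\t")
    pwms = []
    for name, grp in df.groupby("name", sort=False):
        grp = grp.sort_values("position")
        pwms.append(Pwm(str(name), tuple(map(tuple, grp[list(BASES)].to_numpy()))))
    return pwms


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------


@dataclass
class ExtractionConfig:
    """What to extract and the resources each group needs."""

    groups: tuple[str, ...] = ("sequence", "gc", "shape")
    layout: AnnotationLayout = field(default_factory=AnnotationLayout)
    zmodel: ZScoreModel | None = None
    pwms: tuple[Pwm, ...] = ()
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_null: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ConfigurationError("no feature groups selected")
        unknown = set(self.groups) - set(GROUP_ORDER)
        if unknown:
            raise ConfigurationError(f"unknown feature groups {sorted(unknown)}")


@dataclass
class FeatureMatrix:
    """Feature values per variant with schema and per-row chromosome tags."""

    data: pd.DataFrame  # index: variant keys; columns: schema names
    schema: FeatureSchema
    chroms: pd.Series  # aligned with data.index
    labels: pd.Series | None = None  # optional {functional, neutral}

    def __post_init__(self) -> None:
        if list(self.data.columns) != self.schema.names:
            raise SchemaError("matrix columns do not match the schema")
        if self.data.isna().any().any():
            raise SchemaError("feature matrix contains missing entries")

    @property
    def n(self) -> int:
        return len(self.data)

    def y(self) -> np.ndarray:
        """Binary class vector (1 = functional). Requires labels."""
        if self.labels is None:
            raise ContractError("matrix carries no labels")
        return (self.labels == "functional").to_numpy().astype(int)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "variant", self.data.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        schema: FeatureSchema,
        chroms: pd.Series | None = None,
        labels: pd.Series | None = None,
    ) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        df = df.set_index("variant")
        if chroms is None:
            chroms = pd.Series([k.split(":")[0] for k in df.index], index=df.index)
        return cls(df[schema.names], schema, chroms, labels)


def build_matrix(
    variants: Sequence[VariantRecord],
    genome,
    table: PentamerTable | None,
    tracks: Mapping[str, AnnotationTrack] | None,
    config: ExtractionConfig,
) -> FeatureMatrix:
    """Assemble the feature matrix for the selected groups.

    Variants failing any selected extractor (N in window, contig overrun,
    reference mismatch) are excluded with a logged reason.
    """
    schema = FeatureSchema.canonical(config.groups, config.layout)
    needs_annotation = {"histone", "tfbs", "dnase"} & set(config.groups)
    needs_conservation = "conservation" in config.groups
    needs_tf = {"tf_disruption", "tf_maxscore"} & set(config.groups)
    if needs_annotation or needs_conservation:
        if tracks is None:
            raise ConfigurationError("annotation/conservation groups require tracks")
    if needs_conservation:
        if config.zmodel is None:
            raise ConfigurationError("conservation group requires a ZScoreModel")
        for tid in (config.layout.gerp_id, config.layout.phastcons_id):
            if tid not in tracks:
                raise ConfigurationError(f"missing scored track {tid!r}")
    if needs_tf and not config.pwms:
        raise ConfigurationError("TF groups require PWMs")
    if "shape" in config.groups and table is None:
        raise ConfigurationError("shape group requires a pentamer table")

    rows: list[np.ndarray] = []
    keys: list[str] = []
    chrom_tags: list[str] = []
    label_tags: list[str | None] = []
    excluded = 0
    for i, v in enumerate(variants):
        try:
            ref_win = fetch_window(genome, v.chrom, v.pos, SHAPE_WINDOW_FLANK)
            if "N" in ref_win.seq:
                raise ContractError(f"{v.key}: window contains N")
            mut_win = substitute_center(ref_win, v.alt, ref=v.ref)
            parts: list[np.ndarray] = []
            tf_cache: tuple[float, float] | None = None
            ann_cache: np.ndarray | None = None

            def annotation() -> np.ndarray:
                nonlocal ann_cache
                if ann_cache is None:
                    ann_cache = annotation_features(v, tracks, config.layout)
                return ann_cache

            for group in schema.groups:
                if group == "sequence":
                    parts.append(encode_sequence(ref_win.subwindow(4), v.alt))
                elif group == "gc":
                    parts.append(gc_features(ref_win, mut_win))
                elif group == "shape":
                    parts.append(shape_feature_vector(ref_win.seq, mut_win.seq, table))
                elif group == "dinucleotide":
                    parts.append(dinucleotide_features(ref_win.subwindow(4)))
                elif group == "histone":
                    parts.append(annotation()[:38])
                elif group == "tfbs":
                    parts.append(annotation()[38:50])
                elif group in ("tf_disruption", "tf_maxscore"):
                    if tf_cache is None:
                        sub_seed = np.random.SeedSequence(
                            [config.seed, i]
                        ).generate_state(1)[0]
                        tf_cache = tf_motif_features(
                            ref_win,
                            mut_win,
                            config.pwms,
                            config.background,
                            n_null=config.n_null,
                            seed=int(sub_seed),
                        )
                    parts.append(
                        np.array([tf_cache[0 if group == "tf_disruption" else 1]])
                    )
                elif group == "dnase":
                    parts.append(annotation()[50:51])
                elif group == "conservation":
                    parts.append(
                        conservation_features(
                            v,
                            tracks[config.layout.gerp_id],
                            tracks[config.layout.phastcons_id],
                            config.zmodel,
                            ref_win,
                            mut_win,
                        )
                    )
            rows.append(np.concatenate(parts))
            keys.append(v.key)
            chrom_tags.append(v.chrom)
            label_tags.append(v.label)
        except PromshapeError as exc:
            excluded += 1
            logger.info("build_matrix: excluding %s (%s)", v.key, exc)
    if excluded:
        logger.warning("build_matrix: excluded %d of %d variants", excluded, len(variants))

    data = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, len(schema))),
        index=pd.Index(keys, name="variant"),
        columns=schema.names,
    )
    labels = (
        pd.Series(label_tags, index=data.index, dtype=object)
        if any(l is not None for l in label_tags)
        else None
    )
    return FeatureMatrix(data, schema, pd.Series(chrom_tags, index=data.index), labels)
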
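"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the analysis assumes:

* paired tumor/normal WGS read sets over a small synthetic reference
  (telomere-free interiors, terminal telomeric tracts) with a planted
  per-read telomeric fraction of controllable TVR composition, and
  planted intrachromosomal telomere insertions emitting discordant
  pairs and telomeric soft-clipped reads;
* RNA read sets with a planted TERRA-bearing read fraction;
* cohort marker tables with the three TMM subgroups drawn around the
  observed subgroup means (telomere content ratio 0.87 / 6.39 / 0.96
  for TMM- / ALT+ / TEL+; mean TRF 8.39 / 10.66 / 6.36 kb; TERRA
  0.004 / 0.011 / 0.002) and assay flags consistent with the labels
  plus a configurable discordance rate that creates ambiguous cases;
* densitometry lanes whose OD-weighted mean recovers a requested TRF.

Every generator is a pure function of its :class:`SimConfig` (seed
included) and returns a truth record sufficient to score downstream
stages without re-deriving ground truth.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .assays import DensitometryProfile
from .classify import SampleFeatures
from .errors import InputError
from .reads import AlignedRead, reverse_complement
from .tvr import COMMON_TVRS

CANONICAL = "TTAGGG"
SUBGROUPS = ("TMM_neg", "ALT_pos", "TEL_pos")

DEFAULT_TC_MEANS = {"TMM_neg": 0.87, "ALT_pos": 6.39, "TEL_pos": 0.96}
DEFAULT_TRF_MEANS_KB = {"TMM_neg": 8.39, "ALT_pos": 10.66, "TEL_pos": 6.36}
DEFAULT_TERRA_MEANS = {"TMM_neg": 0.004, "ALT_pos": 0.011, "TEL_pos": 0.002}
DEFAULT_N_PER_GROUP = {"TMM_neg": 17, "ALT_pos": 13, "TEL_pos": 31}
# dispersions: lognormal sigma for TC and TERRA (log scale), normal sd (kb)
# for TRF; chosen once to reproduce the assays' observed discriminability
# (near-complete TC separation, partial TERRA overlap) — see docs/methods.md
DEFAULT_TC_SIGMA = 0.6
DEFAULT_TRF_SD_KB = 1.6
DEFAULT_TERRA_SIGMA = 1.2

_SCRUB = re.compile("TTAGGG|CCCTAA")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study. Defaults are the observed
    study conditions (subgroup means and sizes) with read-level
    parameters at desk scale."""

    seed: int = 0
    read_len: int = 100
    n_reads: int = 200_000
    telomeric_fraction: float = 1e-4
    normal_telomeric_fraction: Optional[float] = None  # None -> same as tumor
    tvr_mix: dict = field(
        default_factory=lambda: {
            "TTAGGG": 0.94,
            "TGAGGG": 0.02,
            "TCAGGG": 0.02,
            "TTGGGG": 0.02,
        }
    )
    singleton_rate: float = 0.3  # fraction of telomeric reads carrying one planted singleton
    insertion_sites: tuple = ()  # (chrom, pos, n_pairs, n_clips)
    terra_fraction: float = 0.01
    group_means: dict = field(
        default_factory=lambda: {
            "tc": dict(DEFAULT_TC_MEANS),
            "trf_kb": dict(DEFAULT_TRF_MEANS_KB),
            "terra": dict(DEFAULT_TERRA_MEANS),
        }
    )
    group_sds: dict = field(
        default_factory=lambda: {
            "tc_sigma": DEFAULT_TC_SIGMA,
            "trf_sd_kb": DEFAULT_TRF_SD_KB,
            "terra_sigma": DEFAULT_TERRA_SIGMA,
        }
    )
    n_per_group: dict = field(default_factory=lambda: dict(DEFAULT_N_PER_GROUP))
    discordance_rate: float = 0.1

    def __post_init__(self) -> None:
        total = sum(self.tvr_mix.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-9):
            raise InputError(f"tvr_mix probabilities sum to {total}, not 1")
        if not 0 <= self.telomeric_fraction <= 1:
            raise InputError("telomeric_fraction must be in [0, 1]")
        if self.n_reads <= 0 or self.read_len <= 0:
            raise InputError("n_reads and read_len must be positive")


def make_reference(
    seed: int = 0,
    contig_lengths: Optional[dict[str, int]] = None,
    telomere_len: int = 1200,
) -> dict[str, str]:
    """Small synthetic reference: random interiors scrubbed of t-type
    repeats, with telomeric tracts at both contig ends (C-strand on the
    left, G-strand on the right) so exclusion-BED logic is exercised."""
    rng = np.random.default_rng(seed)
    if contig_lengths is None:
        contig_lengths = {"chr1": 60_000, "chr2": 40_000}
    bases = np.array(list("ACGT"))
    ref = {}
    for chrom, length in contig_lengths.items():
        interior_len = length - 2 * telomere_len
        if interior_len <= 0:
            raise InputError(f"contig {chrom} too short for telomeric tracts")
        interior = "".join(rng.choice(bases, size=interior_len))
        # scrub accidental t-type repeats so interiors are telomere-free
        while True:
            m = _SCRUB.search(interior)
            if not m:
                break
            i = m.start()
            repl = "A" if interior[i] != "A" else "C"
            interior = interior[:i] + repl + interior[i + 1 :]
        left = (reverse_complement(CANONICAL) * (telomere_len // 6 + 1))[:telomere_len]
        right = (CANONICAL * (telomere_len // 6 + 1))[:telomere_len]
        ref[chrom] = left + interior + right
    return ref


def default_exclusion_intervals(
    reference: dict[str, str], telomere_len: int = 1200, pad: int = 300
) -> dict[str, list[tuple[int, int]]]:
    """Exclusion intervals covering the terminal telomeric tracts of a
    synthetic reference (padded), the role the telomere/centromere BED
    plays on a real genome."""
    return {
        chrom: [
            (0, telomere_len + pad),
            (len(seq) - telomere_len - pad, len(seq)),
        ]
        for chrom, seq in reference.items()
    }


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def telomeric_read_seq(
    rng: np.random.Generator,
    read_len: int,
    tvr_mix: dict[str, float],
    singleton_rate: float,
) -> str:
    """A read of tandem hexamers drawn from ``tvr_mix``; with
    probability ``singleton_rate`` one variant hexamer is planted
    mid-read with >= 3 canonical flanks on each side."""
    n_hex = read_len // 6 + 1
    variants = list(tvr_mix)
    probs = np.array([tvr_mix[v] for v in variants])
    hexamers = [variants[i] for i in rng.choice(len(variants), size=n_hex, p=probs)]
    if singleton_rate > 0 and rng.random() < singleton_rate and n_hex >= 7:
        non_canonical = [v for v in variants if v != CANONICAL]
        if non_canonical:
            mid = n_hex // 2
            for k in range(max(0, mid - 3), min(n_hex, mid + 4)):
                hexamers[k] = CANONICAL
            hexamers[mid] = non_canonical[rng.integers(len(non_canonical))]
    seq = "".join(hexamers)[:read_len]
    if rng.random() < 0.5:
        seq = reverse_complement(seq)
    return seq


def _background_pairs(
    rng: np.random.Generator,
    reference: dict[str, str],
    read_len: int,
    n_pairs: int,
    sample_role: str,
    telomere_len: int = 1200,
) -> list[AlignedRead]:
    """Proper mapped pairs drawn from telomere-free contig interiors
    (vectorized position draws; insert size fixed at 300 bp)."""
    if n_pairs == 0:
        return []
    chroms = list(reference)
    weights = np.array([len(reference[c]) for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n_pairs, p=weights / weights.sum())
    lo = np.array([telomere_len + read_len for _ in chroms])
    hi = np.array(
        [len(reference[c]) - telomere_len - 2 * read_len - 400 for c in chroms]
    )
    u = rng.random(n_pairs)
    p1s = (lo[chrom_idx] + u * (hi[chrom_idx] - lo[chrom_idx])).astype(int)
    reads: list[AlignedRead] = []
    for i, (ci, p1) in enumerate(zip(chrom_idx, p1s)):
        chrom = chroms[ci]
        seq = reference[chrom]
        p1 = int(p1)
        p2 = p1 + 300
        rid = f"{sample_role}_bg{i}"
        reads.append(
            AlignedRead(
                read_id=rid,
                seq=seq[p1 : p1 + read_len],
                chrom=chrom,
                pos=p1,
                mate_chrom=chrom,
                mate_pos=p2,
                sample_role=sample_role,
            )
        )
        reads.append(
            AlignedRead(
                read_id=rid,
                seq=reverse_complement(seq[p2 : p2 + read_len]),
                chrom=chrom,
                pos=p2,
                is_reverse=True,
                mate_chrom=chrom,
                mate_pos=p1,
                sample_role=sample_role,
            )
        )
    return reads


def _sample_reads(
    rng: np.random.Generator,
    cfg: SimConfig,
    reference: dict[str, str],
    sample_role: str,
    telomeric_fraction: float,
    insertion_sites: tuple,
) -> tuple[list[AlignedRead], dict]:
    reads: list[AlignedRead] = []
    n_telomeric = int(rng.binomial(cfg.n_reads, telomeric_fraction))
    n_background = cfg.n_reads - n_telomeric

    reads.extend(
        _background_pairs(
            rng, reference, cfg.read_len, n_background // 2, sample_role
        )
    )
    if n_background % 2:  # odd leftover: a single (mate-less) record
        odd = _background_pairs(rng, reference, cfg.read_len, 1, sample_role)[0]
        reads.append(
            AlignedRead(
                read_id=f"{sample_role}_bg_odd",
                seq=odd.seq,
                chrom=odd.chrom,
                pos=odd.pos,
                sample_role=sample_role,
            )
        )

    for i in range(n_telomeric):  # unmapped; paired two by two
        reads.append(
            AlignedRead(
                read_id=f"{sample_role}_telo{i // 2}",
                seq=telomeric_read_seq(
                    rng, cfg.read_len, cfg.tvr_mix, cfg.singleton_rate
                ),
                sample_role=sample_role,
            )
        )

    planted_sites = []
    for site_idx, (chrom, pos, n_pairs, n_clips) in enumerate(insertion_sites):
        seq = reference.get(chrom)
        if seq is None or not 0 < pos < len(seq):
            raise InputError(f"insertion site {chrom}:{pos} outside reference")
        window_start = (pos // 1000) * 1000
        if pos - cfg.read_len <= window_start:
            raise InputError(
                f"insertion site {chrom}:{pos} too close to its 1 kb window "
                f"start; place it at least read_len into the window"
            )
        for j in range(n_pairs):
            anchor = int(
                rng.integers(max(window_start, pos - 400), pos - cfg.read_len)
            )
            rid = f"{sample_role}_ins{site_idx}_pair{j}"
            reads.append(
                AlignedRead(
                    read_id=rid,
                    seq=seq[anchor : anchor + cfg.read_len],
                    chrom=chrom,
                    pos=anchor,
                    mate_chrom=None,
                    mate_pos=None,
                    sample_role=sample_role,
                )
            )
            reads.append(
                AlignedRead(
                    read_id=rid,
                    seq=telomeric_read_seq(rng, cfg.read_len, cfg.tvr_mix, 0.0),
                    sample_role=sample_role,
                )
            )
        clip_len = 21  # >= 15 bp and >= 2 t-type repeats guaranteed
        aligned_len = cfg.read_len - clip_len
        for j in range(n_clips):
            clip_seq = (CANONICAL * 4)[:clip_len]
            reads.append(
                AlignedRead(
                    read_id=f"{sample_role}_ins{site_idx}_clip{j}",
                    seq=seq[pos - aligned_len : pos] + clip_seq,
                    chrom=chrom,
                    pos=pos - aligned_len,
                    clip_right_len=clip_len,
                    clip_right_seq=clip_seq,
                    sample_role=sample_role,
                )
            )
        planted_sites.append(
            {"chrom": chrom, "pos": pos, "n_pairs": n_pairs, "n_clips": n_clips}
        )

    truth = {
        "n_reads": len(reads),
        "n_telomeric": n_telomeric,
        "telomeric_fraction": telomeric_fraction,
        "insertion_sites": planted_sites,
    }
    return reads, truth


def simulate_wgs_pair(
    cfg: SimConfig, reference: Optional[dict[str, str]] = None
) -> tuple[list[AlignedRead], list[AlignedRead], dict]:
    """Paired tumor/normal WGS read sets plus a truth record.

    The tumor carries the planted telomeric fraction, TVR/singleton
    composition and insertion sites; the normal shares the reference
    and its own telomeric fraction but no insertions.
    """
    rng = np.random.default_rng(cfg.seed)
    if reference is None:
        reference = make_reference(seed=cfg.seed)
    normal_fraction = (
        cfg.telomeric_fraction
        if cfg.normal_telomeric_fraction is None
        else cfg.normal_telomeric_fraction
    )
    tumor, tumor_truth = _sample_reads(
        rng, cfg, reference, "tumor", cfg.telomeric_fraction, cfg.insertion_sites
    )
    normal, normal_truth = _sample_reads(
        rng, cfg, reference, "normal", normal_fraction, ()
    )
    truth = {
        "tumor": tumor_truth,
        "normal": normal_truth,
        "reference_lengths": {c: len(s) for c, s in reference.items()},
    }
    return tumor, normal, truth


def simulate_rna_reads(cfg: SimConfig) -> tuple[list[AlignedRead], dict]:
    """RNA read set with a planted TERRA-bearing fraction; each TERRA
    read embeds >= 4 tandem copies of one common TVR (either strand)
    inside random sequence."""
    rng = np.random.default_rng(cfg.seed)
    variants = [v for v in COMMON_TVRS if v in cfg.tvr_mix]
    probs = np.array([cfg.tvr_mix[v] for v in variants])
    probs = probs / probs.sum()
    reads = []
    per_variant = {v: 0 for v in variants}
    n_terra = int(rng.binomial(cfg.n_reads, cfg.terra_fraction))
    for i in range(cfg.n_reads):
        if i < n_terra:
            v = variants[rng.choice(len(variants), p=probs)]
            insert = v * 5
            pad = cfg.read_len - len(insert)
            left = int(rng.integers(0, pad + 1))
            seq = (
                _random_seq(rng, left)
                + insert
                + _random_seq(rng, pad - left)
            )
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            per_variant[v] += 1
        else:
            seq = _random_seq(rng, cfg.read_len)
        reads.append(
            AlignedRead(read_id=f"rna{i}", seq=seq, sample_role="tumor")
        )
    truth = {
        "n_reads": cfg.n_reads,
        "terra_fraction": cfg.terra_fraction,
        "n_terra": n_terra,
        "per_variant": per_variant,
    }
    return reads, truth


def _lognormal_around_mean(
    rng: np.random.Generator, mean: float, sigma: float, size: int
) -> np.ndarray:
    """Lognormal draws whose arithmetic mean equals ``mean``."""
    mu = math.log(mean) - sigma**2 / 2.0
    return rng.lognormal(mu, sigma, size=size)


def simulate_cohort_table(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """Cohort marker table (one row per sample, columns matching
    :class:`~telotype.classify.SampleFeatures`) plus truth labels.

    Subgroup metric distributions: lognormal telomere content and TERRA
    around the subgroup means, normal TRF. Assay flags are consistent
    with the truth label except that with probability
    ``discordance_rate`` one APB/CCA/TERT flag is flipped, creating the
    ambiguous strict calls seen in real cohorts.
    """
    for group, n in cfg.n_per_group.items():
        if n < 2:
            raise InputError(f"n_per_group[{group!r}] must be >= 2")
    rng = np.random.default_rng(cfg.seed)
    tc_means = cfg.group_means["tc"]
    trf_means = cfg.group_means["trf_kb"]
    terra_means = cfg.group_means["terra"]
    tc_sigma = cfg.group_sds["tc_sigma"]
    trf_sd = cfg.group_sds["trf_sd_kb"]
    terra_sigma = cfg.group_sds["terra_sigma"]

    rows = []
    labels = []
    idx = 0
    for group in SUBGROUPS:
        n = cfg.n_per_group[group]
        tc = _lognormal_around_mean(rng, tc_means[group], tc_sigma, n)
        trf = rng.normal(trf_means[group], trf_sd, size=n).clip(min=1.0)
        terra = _lognormal_around_mean(rng, terra_means[group], terra_sigma, n)
        for k in range(n):
            idx += 1
            alt = group == "ALT_pos"
            tel = group == "TEL_pos"
            mna = bool(tel and rng.random() < 0.3)
            tert_ra = bool(tel and not mna and rng.random() < 0.3)
            row = {
                "sample_id": f"S{idx:03d}",
                "mna": mna,
                "tert_ra": tert_ra,
                "atrx_mut": bool(alt and rng.random() < 0.46),
                "tert_expr_high": tel,
                "telomerase_activity_high": bool(tel and rng.random() < 0.9),
                "apb": alt,
                "cca": alt,
                "tc_ratio": float(tc[k]),
                "trf_kb": float(trf[k]),
                "terra_total": float(terra[k]),
                "ttt_ggg_singleton_log2": float(
                    rng.normal(-2.0 if alt else 0.0, 0.6)
                ),
                "n_insertions": int(
                    (1 + rng.poisson(2))
                    if rng.random() < {"ALT_pos": 0.77, "TEL_pos": 0.32, "TMM_neg": 0.06}[group]
                    else 0
                ),
            }
            if rng.random() < cfg.discordance_rate:
                flipped = str(rng.choice(["apb", "cca"]))
                row[flipped] = not alt  # false-negative in ALT+, false-positive otherwise
            rows.append(row)
            labels.append(group)
    frame = pd.DataFrame(rows).set_index("sample_id", drop=False)
    return frame, pd.Series(labels, index=frame.index, name="truth")


def features_from_row(row: pd.Series) -> SampleFeatures:
    """Build SampleFeatures from one cohort-table row (NA -> None)."""

    def opt(name, cast):
        if name not in row or pd.isna(row[name]):
            return None
        return cast(row[name])

    return SampleFeatures(
        sample_id=str(row["sample_id"]),
        mna=opt("mna", bool),
        tert_ra=opt("tert_ra", bool),
        atrx_mut=opt("atrx_mut", bool),
        tert_expr_high=opt("tert_expr_high", bool),
        telomerase_activity_high=opt("telomerase_activity_high", bool),
        apb=opt("apb", bool),
        cca=opt("cca", bool),
        tc_ratio=opt("tc_ratio", float),
        trf_kb=opt("trf_kb", float),
        terra_total=opt("terra_total", float),
        ttt_ggg_singleton_log2=opt("ttt_ggg_singleton_log2", float),
        n_insertions=opt("n_insertions", int),
    )


def simulate_densitometry(
    mean_kb: float,
    sd_kb: float,
    n_points: int = 60,
    seed: int = 0,
    lane_range_kb: tuple[float, float] = (2.0, 20.0),
    noise: float = 0.01,
) -> DensitometryProfile:
    """Gaussian OD profile over a log-spaced fragment ladder whose
    OD-weighted mean recovers ``mean_kb``.

    Band signal is density times local ladder spacing, so the discrete
    weighted mean is unbiased on the non-uniform grid; multiplicative
    lane noise of relative size ``noise`` is seeded.
    """
    if sd_kb <= 0:
        raise InputError("sd_kb must be positive")
    lo, hi = lane_range_kb
    if not lo < mean_kb < hi:
        raise InputError(f"mean_kb {mean_kb} outside lane range {lane_range_kb}")
    rng = np.random.default_rng(seed)
    ladder = np.geomspace(lo, hi, n_points)
    density = np.exp(-0.5 * ((ladder - mean_kb) / sd_kb) ** 2)
    od = density * np.gradient(ladder)
    od = od * (1.0 + noise * rng.standard_normal(n_points))
    od = np.clip(od, 0.0, None)
    # descending fragment length down the lane, as on a blot
    lanes = tuple(
        (float(length), float(o)) for length, o in zip(ladder[::-1], od[::-1])
    )
    return DensitometryProfile(lanes=lanes)


def cohort_with_discordance(cfg: SimConfig, rate: float) -> SimConfig:
    """Convenience: a copy of ``cfg`` with another discordance rate."""
    return replace(cfg, discordance_rate=rate)
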
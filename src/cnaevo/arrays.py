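"""Probe-level SNP-array signal emulation (logR + BAF) for clone mixtures.

A clone mixture is converted to per-haplotype copy numbers at each probe,
then to the two standard array summaries: logR (log2 of total copy number
over a reference ploidy, diploid-centered by default) and BAF (B-allele
fraction, with heterozygous probes splitting into mirrored bands under
allelic imbalance).  Gaussian probe noise is added independently per probe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeBuild
from .simulate import CloneTruth

__all__ = [
    "ProbeMap",
    "ProbeSignal",
    "make_probe_map",
    "clone_copy_profile",
    "mixture_copy_numbers",
    "expected_logr",
    "expected_baf",
    "emulate_sample",
    "DEFAULT_NOISE",
    "LOGR_FLOOR",
]

#: (sigma_logr, sigma_baf) defaults for a decent-quality genotyping array.
DEFAULT_NOISE = (0.15, 0.03)
#: logR reported when total copy number is 0 (homozygous deletion).
LOGR_FLOOR = -5.0


@dataclass
class ProbeMap:
    """Probe positions plus per-probe genotype bookkeeping.

    ``het`` flags heterozygous (AB) probes; for those, ``b_on_hap`` says
    which homolog (0/1) carries the B allele.  For homozygous probes
    ``hom_is_b`` says whether the genotype is BB (BAF near 1) or AA (near 0).
    """

    positions: dict[str, np.ndarray]
    het: dict[str, np.ndarray]
    b_on_hap: dict[str, np.ndarray]
    hom_is_b: dict[str, np.ndarray]

    @property
    def chroms(self) -> list[str]:
        return list(self.positions)

    @property
    def n_probes(self) -> int:
        return sum(len(v) for v in self.positions.values())

    def swapped_b(self) -> "ProbeMap":
        """Mirror the B-allele haplotype assignment (BAF -> 1 - BAF)."""
        return ProbeMap(
            positions=self.positions,
            het=self.het,
            b_on_hap={c: 1 - v for c, v in self.b_on_hap.items()},
            hom_is_b={c: ~v for c, v in self.hom_is_b.items()},
        )


def make_probe_map(
    genome: GenomeBuild,
    spacing: int = 50_000,
    het_fraction: float = 0.3,
    seed: int = 0,
) -> ProbeMap:
    """Uniformly spaced probes (default 1 / 50 kb), random het status."""
    rng = np.random.default_rng(seed)
    positions, het, b_on, hom_b = {}, {}, {}, {}
    for name, length in genome.chromosomes:
        pos = np.arange(spacing // 2, length, spacing, dtype=np.int64)
        positions[name] = pos
        het[name] = rng.random(len(pos)) < het_fraction
        b_on[name] = rng.integers(0, 2, len(pos)).astype(np.int8)
        hom_b[name] = rng.random(len(pos)) < 0.5
    return ProbeMap(positions, het, b_on, hom_b)


@dataclass
class ProbeSignal:
    """Per-probe logR and BAF for one sample."""

    sample_id: str
    positions: dict[str, np.ndarray]
    logr: dict[str, np.ndarray]
    baf: dict[str, np.ndarray]
    het: dict[str, np.ndarray]

    @property
    def chroms(self) -> list[str]:
        return list(self.positions)

    @property
    def n_probes(self) -> int:
        return sum(len(v) for v in self.positions.values())

    def genome_logr(self) -> np.ndarray:
        return np.concatenate([self.logr[c] for c in self.chroms])


def clone_copy_profile(
    truth: CloneTruth, clone_id: str, chrom: str, positions: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-haplotype copy numbers of one clone at the given positions.

    Events are applied in acquisition order along the lineage: wgd doubles
    both homologs; a gain/loss adds/removes copies on its homolog; cn-LOH
    transfers the affected homolog's copies to the other (0 on one side,
    doubled on the other, at diploid baseline).  A ``complex`` event is
    emulated as a +1 gain on homolog A over its left half stacked with a
    -1 loss on homolog B over its right half.
    """
    cn = np.ones((2, len(positions)), dtype=float)
    for eid in truth.lineage_events(clone_id):
        ev = truth.events[eid]
        if ev.kind == "wgd":
            cn *= 2.0
            continue
        seg = ev.segment
        assert seg is not None
        if seg.chrom != chrom:
            continue
        mask = (positions >= seg.start) & (positions < seg.end)
        if not mask.any():
            continue
        hap = truth.event_haplotype.get(eid, 0)
        if ev.kind == "gain":
            cn[hap, mask] += ev.copy_delta
        elif ev.kind == "loss":
            cn[hap, mask] = np.maximum(0.0, cn[hap, mask] + ev.copy_delta)
        elif ev.kind == "cnloh":
            cn[1 - hap, mask] += cn[hap, mask]
            cn[hap, mask] = 0.0
        elif ev.kind == "complex":
            mid = (seg.start + seg.end) // 2
            left = mask & (positions < mid)
            right = mask & (positions >= mid)
            cn[hap, left] += 1.0
            cn[1 - hap, right] = np.maximum(0.0, cn[1 - hap, right] - 1.0)
    return cn[0], cn[1]


def _mixture_profiles(
    truth: CloneTruth, passage: int, chrom: str, positions: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    if passage not in truth.fractions:
        raise KeyError(f"passage {passage} was not simulated")
    cn_a = np.zeros(len(positions))
    cn_b = np.zeros(len(positions))
    for cid, frac in truth.fractions[passage].items():
        if frac <= 0:
            continue
        a, b = clone_copy_profile(truth, cid, chrom, positions)
        cn_a += frac * a
        cn_b += frac * b
    return cn_a, cn_b


def mixture_copy_numbers(
    truth: CloneTruth, passage: int, chrom: str, position: int
) -> tuple[float, float]:
    """Mixture-averaged per-haplotype copy numbers at one genomic position."""
    if chrom not in truth.genome:
        raise KeyError(f"unknown chromosome {chrom!r}")
    if not (0 <= position < truth.genome.length(chrom)):
        raise ValueError(f"position {position} outside {chrom}")
    a, b = _mixture_profiles(truth, passage, chrom, np.array([position]))
    return float(a[0]), float(b[0])


def expected_logr(
    major: float | np.ndarray,
    minor: float | np.ndarray,
    reference_ploidy: float = 2.0,
    floor: float = LOGR_FLOOR,
) -> float | np.ndarray:
    """log2((major + minor) / reference_ploidy); the configured floor when
    total copy number is 0."""
    if reference_ploidy <= 0:
        raise ValueError("reference_ploidy must be > 0")
    total = np.asarray(major, dtype=float) + np.asarray(minor, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(total > 0, np.log2(np.maximum(total, 1e-300) / reference_ploidy), floor)
    return float(out) if out.ndim == 0 else out


def expected_baf(
    cn_hap0: float | np.ndarray,
    cn_hap1: float | np.ndarray,
    b_on_hap: int | np.ndarray,
) -> float | np.ndarray:
    """B copies over total copies at a heterozygous probe; 0.5 when the
    total is 0 (no signal, by convention)."""
    a = np.asarray(cn_hap0, dtype=float)
    b = np.asarray(cn_hap1, dtype=float)
    hap = np.asarray(b_on_hap)
    total = a + b
    b_copies = np.where(hap == 0, a, b)
    out = np.where(total > 0, b_copies / np.where(total > 0, total, 1.0), 0.5)
    return float(out) if out.ndim == 0 else out


def emulate_sample(
    truth: CloneTruth,
    passage: int,
    probemap: ProbeMap,
    noise: tuple[float, float] = DEFAULT_NOISE,
    seed: int = 0,
    sample_id: str | None = None,
    centering: str = "diploid",
) -> ProbeSignal:
    """Noisy probe-level signal for the clone mixture at one passage.

    ``centering="diploid"`` leaves logR on the diploid reference scale;
    ``"median"`` re-centers logR at the genome-wide median (what many real
    pipelines do, and what makes absolute ploidy unidentifiable without a
    grid fit).  Deterministic given ``seed``.
    """
    if centering not in ("diploid", "median"):
        raise ValueError("centering must be 'diploid' or 'median'")
    sigma_logr, sigma_baf = noise
    rng = np.random.default_rng(seed)
    logr: dict[str, np.ndarray] = {}
    baf: dict[str, np.ndarray] = {}
    for chrom in probemap.chroms:
        pos = probemap.positions[chrom]
        cn_a, cn_b = _mixture_profiles(truth, passage, chrom, pos)
        lr = np.asarray(expected_logr(cn_a, cn_b), dtype=float)
        het = probemap.het[chrom]
        bf = np.asarray(
            expected_baf(cn_a, cn_b, probemap.b_on_hap[chrom]), dtype=float
        )
        # homozygous probes sit at BAF 0 (AA) or 1 (BB) regardless of CN
        bf = np.where(het, bf, np.where(probemap.hom_is_b[chrom], 1.0, 0.0))
        if sigma_logr > 0:
            lr = lr + rng.normal(0.0, sigma_logr, len(pos))
        if sigma_baf > 0:
            bf = bf + rng.normal(0.0, sigma_baf, len(pos))
        logr[chrom] = lr
        baf[chrom] = np.clip(bf, 0.0, 1.0)
    if centering == "median":
        med = float(np.median(np.concatenate(list(logr.values()))))
        logr = {c: v - med for c, v in logr.items()}
    return ProbeSignal(
        sample_id=sample_id or f"P{passage}",
        positions={c: probemap.positions[c] for c in probemap.chroms},
        logr=logr,
        baf=baf,
        het={c: probemap.het[c].copy() for c in probemap.chroms},
    )
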
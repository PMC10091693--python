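"""CNA event calling from probe-level logR/BAF signal.

The stage chain is: recursive segmentation of logR (accept the interval
whose two-sample t-statistic against its complement exceeds a
Bonferroni-corrected critical value, then recurse on the parts),
mirrored BAF band fitting per segment, state calling (gain / loss / cn-LOH /
complex / neutral), per-event MCF estimation from standard mixture
identities, average-ploidy grid fitting for whole-genome-duplication
detection, and cross-sample unification of events into the event x sample
MCF matrix.

MCF identities (diploid baseline, clone fraction f):

* one-copy loss:   logR = log2((2 - f)/2)     ->  f = 2 (1 - 2^logR)
                   lower het band b = (1-f)/(2-f)  ->  f = (1 - 2b)/(1 - b)
* one-copy gain:   logR = log2((2 + f)/2)     ->  f = 2 (2^logR - 1)
                   upper het band b = (1+f)/(2+f)  ->  f = (2b - 1)/(1 - b)
* cn-LOH:          logR = 0, lower band b = (1-f)/2  ->  f = 1 - 2b

The BAF route is preferred when enough heterozygous probes are available —
it is free of the logR ploidy baseline; the logR route is the fallback.
Events whose estimated MCF does not exceed the clone-size detectability
floor (default 10%) are not emitted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .arrays import ProbeSignal
from .genome import CNAEvent, GenomeBuild, GenomicSegment, reciprocal_overlap
from .matrix import EventMatrix, event_row_label

__all__ = [
    "CallThresholds",
    "CalledSegment",
    "PloidyCall",
    "segment_signal",
    "fit_baf_bands",
    "estimate_baf_noise",
    "call_events",
    "estimate_mcf",
    "detect_wgd",
    "build_event_matrix",
    "call_sample",
    "CLONE_SIZE_FLOOR",
]

#: Minimum clone fraction for an alteration to be emitted (array
#: detectability: a clone must exceed ~10% of cells to be visible).
CLONE_SIZE_FLOOR = 0.10


@dataclass(frozen=True)
class CallThresholds:
    """Event-calling thresholds.

    Defaults are chosen so that the clone-size detectability floor, not the
    logR/BAF cutoffs, is the binding constraint for >= 1 Mbp events.
    """

    t_gain: float = 0.1
    t_loss: float = 0.1
    t_neutral: float = 0.05
    b_split: float = 0.06          # min band separation (upper - lower) for cn-LOH
    clone_size_floor: float = CLONE_SIZE_FLOOR
    min_het_probes: int = 10
    complex_tol: float = 0.35      # |f_baf - f_logr| beyond this -> complex
    reference_ploidy: float = 2.0


@dataclass
class CalledSegment:
    """One segment of constant copy-number state in one sample."""

    segment: GenomicSegment
    mean_logr: float
    baf_bands: tuple[float, ...]   # (lower, upper) mirrored around 0.5, or (0.5,)
    n_probes: int
    n_het: int = 0
    call: str = "neutral"
    mcf: float | None = None
    sample_id: str = ""
    annotations: dict = field(default_factory=dict)

    @property
    def band_split(self) -> float:
        if len(self.baf_bands) < 2:
            return 0.0
        return self.baf_bands[-1] - self.baf_bands[0]


@dataclass(frozen=True)
class PloidyCall:
    """Average-ploidy fit: psi_hat = fitted mean total copy number."""

    psi_hat: float
    wgd_flag: bool
    fit_score: float


# ---------------------------------------------------------------------------
# segmentation


def _best_interval(x: np.ndarray, min_probes: int) -> tuple[int, int, float, int] | None:
    """Best interval [i, j) by pooled t-statistic of interval vs complement.

    Scans every candidate interval with >= ``min_probes`` probes inside and
    outside (a plain binary split is the special case of an interval
    touching a region boundary; scanning intervals keeps power for events
    interior to a region, which a single split dilutes).  Returns
    (i, j, |t|, number of candidate intervals), or None if the region is
    too short.
    """
    n = len(x)
    if n < 2 * min_probes:
        return None
    cs = np.concatenate([[0.0], np.cumsum(x)])
    css = np.concatenate([[0.0], np.cumsum(x * x)])
    total, ss_total = cs[-1], css[-1]
    best_t, best_ij = -1.0, (0, n)
    ncand = 0
    denom = float(max(n - 2, 1))
    for length in range(min_probes, n - min_probes + 1):
        starts = np.arange(0, n - length + 1)
        ncand += len(starts)
        sum_in = cs[starts + length] - cs[starts]
        ss_in = css[starts + length] - css[starts]
        n_out = n - length
        mean_in = sum_in / length
        mean_out = (total - sum_in) / n_out
        ssd_in = ss_in - sum_in**2 / length
        ssd_out = (ss_total - ss_in) - (total - sum_in) ** 2 / n_out
        sp2 = np.maximum(ssd_in + ssd_out, 0.0) / denom
        se = np.sqrt(np.maximum(sp2 * (1.0 / length + 1.0 / n_out), 1e-24))
        t = np.abs(mean_in - mean_out) / se
        k = int(np.argmax(t))
        if t[k] > best_t:
            best_t = float(t[k])
            best_ij = (int(starts[k]), int(starts[k]) + length)
    return best_ij[0], best_ij[1], best_t, ncand


def _split_region(
    x: np.ndarray, lo: int, hi: int, min_probes: int, alpha: float
) -> list[int]:
    """Recursive interval segmentation; returns sorted interior breakpoints."""
    out: list[int] = []
    stack = [(lo, hi)]
    while stack:
        a, b = stack.pop()
        res = _best_interval(x[a:b], min_probes)
        if res is None:
            continue
        i, j, tmax, ncand = res
        df = max(b - a - 2, 1)
        crit = sps.t.ppf(1.0 - alpha / (2.0 * ncand), df)
        if tmax <= crit:
            continue
        for cut in (a + i, a + j):
            if a < cut < b:
                out.append(cut)
        parts = sorted({a, a + i, a + j, b})
        for p, q in zip(parts[:-1], parts[1:]):
            if q - p >= 2 * min_probes and (p, q) != (a, b):
                stack.append((p, q))
    return sorted(out)


def estimate_baf_noise(signal: ProbeSignal) -> float:
    """Sample-level BAF noise sd, estimated from homozygous probes.

    Homozygous probes sit at BAF 0 or 1 regardless of copy number; after
    clipping to [0, 1] the folded residual min(BAF, 1-BAF) retains half of
    the Gaussian mass, so sigma^2 = 2 * E[min(BAF, 1-BAF)^2].
    """
    resid = []
    for chrom in signal.chroms:
        hom = ~signal.het[chrom]
        if hom.any():
            b = signal.baf[chrom][hom]
            resid.append(np.minimum(b, 1.0 - b))
    if not resid:
        return 0.0
    r = np.concatenate(resid)
    return float(np.sqrt(2.0 * np.mean(r**2)))


def fit_baf_bands(baf_het: np.ndarray, sigma_baf: float) -> tuple[float, ...]:
    """Mirrored het-BAF band centers 0.5 +/- m for one segment.

    The half-split m is the moment estimate sqrt(max(0, E[(BAF-0.5)^2] -
    sigma^2)): exact on noiseless signal, unbiased under balanced mirrored
    bands.  Returns (0.5,) when no heterozygous probes are available.
    """
    if len(baf_het) == 0:
        return (0.5,)
    x = np.asarray(baf_het, dtype=float) - 0.5
    m2 = float(np.mean(x**2)) - sigma_baf**2
    m = float(np.sqrt(max(m2, 0.0)))
    m = min(m, 0.5)
    return (0.5 - m, 0.5 + m)


def segment_signal(
    signal: ProbeSignal,
    min_probes: int = 10,
    alpha: float = 0.01,
    merge_tol: float = 0.1,
    band_merge_tol: float = 0.05,
) -> list[CalledSegment]:
    """Segment one sample's logR track chromosome by chromosome.

    A candidate interval is accepted when its two-sample t-statistic
    against the rest of the region exceeds the Bonferroni critical value
    for level ``alpha`` over candidate intervals, with >= ``min_probes``
    probes inside and outside; recursion continues on the resulting parts.
    The same scan runs on the folded heterozygous-BAF track (|BAF - 0.5|),
    whose breakpoints are pooled with the logR ones — copy-neutral LOH
    shifts BAF while leaving logR flat, so logR alone cannot place its
    boundaries.  Adjacent segments are merged back only when both mean
    logR (within ``merge_tol``) and band half-split (within
    ``band_merge_tol``) agree.  Chromosomes with fewer than
    2 * ``min_probes`` probes yield a single segment.  Band centers are
    fitted from the segment's heterozygous probes with the sample-level
    BAF noise estimate.
    """
    sigma_baf = estimate_baf_noise(signal)
    out: list[CalledSegment] = []
    for chrom in signal.chroms:
        x = signal.logr[chrom]
        pos = signal.positions[chrom]
        het = signal.het[chrom]
        baf = signal.baf[chrom]
        n = len(x)
        if n == 0:
            continue
        breaks = set(
            _split_region(x, 0, n, min_probes, alpha) if n >= 2 * min_probes else []
        )
        # cn-LOH leaves logR flat: segment the folded het-BAF track too and
        # pool the breakpoints (mapped back to all-probe indices)
        het_idx = np.nonzero(het)[0]
        if len(het_idx) >= 2 * min_probes:
            folded = np.abs(baf[het_idx] - 0.5)
            for k in _split_region(folded, 0, len(het_idx), min_probes, alpha):
                breaks.add(int(het_idx[k]))
        bounds = [0] + sorted(breaks) + [n]
        # pooled logR/BAF breakpoints can sit closer than min_probes apart;
        # absorb short fragments into the neighbour with the closer mean
        changed = True
        while changed and len(bounds) > 2:
            changed = False
            sizes = np.diff(bounds)
            k = int(np.argmin(sizes))
            if sizes[k] < min_probes:
                a, b = bounds[k], bounds[k + 1]
                frag = float(np.mean(x[a:b]))
                left = (abs(frag - float(np.mean(x[bounds[k - 1]:a])))
                        if k > 0 else np.inf)
                right = (abs(frag - float(np.mean(x[b:bounds[k + 2]])))
                         if k + 2 < len(bounds) else np.inf)
                del bounds[k + 1 if right <= left else k]
                changed = True

        def band_m(a: int, b: int) -> float:
            hb = baf[a:b][het[a:b]]
            bands = fit_baf_bands(hb, sigma_baf)
            return (bands[-1] - bands[0]) / 2.0 if len(bands) > 1 else 0.0

        # merge adjacent segments agreeing in BOTH mean logR and band split
        merged: list[tuple[int, int]] = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            if merged:
                pa, pb = merged[-1]
                if (abs(np.mean(x[pa:pb]) - np.mean(x[a:b])) < merge_tol
                        and abs(band_m(pa, pb) - band_m(a, b)) < band_merge_tol):
                    merged[-1] = (pa, b)
                    continue
            merged.append((a, b))
        chrom_len_end = int(pos[-1]) + 1
        for a, b in merged:
            start = 0 if a == 0 else int((pos[a - 1] + pos[a]) // 2)
            end = chrom_len_end if b == n else int((pos[b - 1] + pos[b]) // 2)
            het_baf = baf[a:b][het[a:b]]
            out.append(
                CalledSegment(
                    segment=GenomicSegment(chrom, start, end),
                    mean_logr=float(np.mean(x[a:b])),
                    baf_bands=fit_baf_bands(het_baf, sigma_baf),
                    n_probes=b - a,
                    n_het=int(het[a:b].sum()),
                    sample_id=signal.sample_id,
                )
            )
    return out


# ---------------------------------------------------------------------------
# state calling and MCF estimation


def _mcf_from_logr(call: str, rebased_logr: float, ref: float = 2.0) -> float:
    # single-step change of one copy on a baseline of ref total copies:
    # loss  logR = log2((ref - f)/ref)  ->  f = ref (1 - 2^logR)
    # gain  logR = log2((ref + f)/ref)  ->  f = ref (2^logR - 1)
    if call == "loss":
        return ref * (1.0 - 2.0**rebased_logr)
    if call == "gain":
        return ref * (2.0**rebased_logr - 1.0)
    if call == "cnloh":
        return float("nan")  # logR carries no cn-LOH signal
    raise ValueError(f"MCF undefined for call {call!r}")


def _mcf_from_baf(call: str, bands: tuple[float, ...], ref: float = 2.0) -> float:
    # c copies per homolog at baseline (c = ref/2); one-copy change on one
    # homolog at clone fraction f:
    # loss  b = (c - f)/(ref - f)  ->  f = c (1 - 2b)/(1 - b)
    # gain  b = (c + f)/(ref + f)  ->  f = c (2b - 1)/(1 - b)
    # cn-LOH is baseline-free: b = (1 - f)/2  ->  f = 1 - 2b
    if len(bands) < 2:
        return float("nan")
    c = ref / 2.0
    lower, upper = bands[0], bands[-1]
    if call == "loss":
        if lower >= 0.5:
            return 0.0
        return c * (1.0 - 2.0 * lower) / (1.0 - lower)
    if call == "gain":
        if upper >= 1.0:
            return 1.0
        return c * (2.0 * upper - 1.0) / (1.0 - upper)
    if call == "cnloh":
        return 1.0 - 2.0 * lower
    raise ValueError(f"MCF undefined for call {call!r}")


def estimate_mcf(
    seg: CalledSegment,
    reference_ploidy: float = 2.0,
    min_het_probes: int = 10,
) -> float:
    """Mutated cell fraction of a gain / loss / cn-LOH segment.

    ``reference_ploidy`` is the sample's baseline total copy number (2 for
    a diploid sample, 4 after a clonal genome doubling): the logR track is
    rebased by -log2(ref/2) and the single-step identities are scaled to
    the baseline.  Uses the BAF band identity when the segment has at
    least ``min_het_probes`` heterozygous probes, otherwise the logR
    identity; the result is clipped to [0, 1].  Raises for neutral or
    complex calls, whose MCF is undefined.
    """
    if seg.call not in ("gain", "loss", "cnloh"):
        raise ValueError(f"MCF undefined for call {seg.call!r}")
    f = float("nan")
    # cn-LOH has no logR signal: the BAF route is used whenever any het
    # probes exist, not only above the preference threshold
    if seg.n_het >= min_het_probes or (seg.call == "cnloh" and seg.n_het > 0):
        f = _mcf_from_baf(seg.call, seg.baf_bands, reference_ploidy)
    if not np.isfinite(f):
        logr = seg.mean_logr - np.log2(reference_ploidy / 2.0)
        f = _mcf_from_logr(seg.call, logr, reference_ploidy)
    if not np.isfinite(f):
        raise ValueError(
            f"cannot estimate MCF for {seg.call} segment without het probes"
        )
    return float(np.clip(f, 0.0, 1.0))


def _classify(seg: CalledSegment, th: CallThresholds,
              reference_ploidy: float | None = None) -> str:
    ref = reference_ploidy if reference_ploidy is not None \
        else th.reference_ploidy
    lr = seg.mean_logr - np.log2(ref / 2.0)
    if lr > th.t_gain:
        call = "gain"
    elif lr < -th.t_loss:
        call = "loss"
    elif (abs(lr) <= th.t_neutral and seg.band_split >= th.b_split
          and seg.n_het >= th.min_het_probes):
        call = "cnloh"
    else:
        return "neutral"
    # band / logR consistency: both routes should tell a compatible story
    if call in ("gain", "loss") and seg.n_het >= th.min_het_probes:
        f_baf = _mcf_from_baf(call, seg.baf_bands, ref)
        f_logr = _mcf_from_logr(call, lr, ref)
        if np.isfinite(f_baf) and np.isfinite(f_logr):
            if abs(f_baf - f_logr) > th.complex_tol:
                return "complex"
    return call


def call_events(
    segments: list[CalledSegment],
    thresholds: CallThresholds | None = None,
    reference_ploidy: float | None = None,
) -> list[tuple[CNAEvent, float]]:
    """Call CNA events on one sample's segments; returns (event, MCF) pairs.

    ``reference_ploidy`` overrides the thresholds' baseline total copy
    number — pass 4.0 for a sample whose ploidy fit flagged a clonal
    genome doubling, so events are called relative to the doubled genome.
    Segments are classified in place (``seg.call`` / ``seg.mcf``); neutral
    segments are dropped, complex segments are emitted with NaN MCF
    (annotated, never placed in trees), and gain/loss/cn-LOH events whose
    estimated MCF does not exceed the clone-size floor are suppressed.
    """
    th = thresholds or CallThresholds()
    ref = reference_ploidy if reference_ploidy is not None \
        else th.reference_ploidy
    out: list[tuple[CNAEvent, float]] = []
    for seg in segments:
        call = _classify(seg, th, ref)
        seg.call = call
        if call == "neutral":
            seg.mcf = None
            continue
        if call == "complex":
            seg.mcf = None
            ev = CNAEvent(
                f"{seg.sample_id}:{event_row_label_for(seg)}", "complex",
                seg.segment, 0,
            )
            out.append((ev, float("nan")))
            continue
        f = estimate_mcf(seg, ref, th.min_het_probes)
        seg.mcf = f
        if f <= th.clone_size_floor:
            continue
        delta = {"gain": 1, "loss": -1}.get(call, 0)
        ev = CNAEvent(
            f"{seg.sample_id}:{event_row_label_for(seg)}", call, seg.segment, delta
        )
        out.append((ev, f))
    return out


def event_row_label_for(seg: CalledSegment) -> str:
    s = seg.segment
    return f"{s.chrom}:{s.start + 1}-{s.end}:{seg.call}"


# ---------------------------------------------------------------------------
# whole-genome-duplication detection


def _allele_split(bands: tuple[float, ...]) -> float:
    """Major-allele signal fraction (upper band center, >= 0.5)."""
    if len(bands) < 2:
        return 0.5
    return max(bands[-1], 0.5)


def detect_wgd(
    segments: list[CalledSegment],
    genome: GenomeBuild,
    psi_grid: tuple[float, float, float] = (1.5, 5.0, 0.05),
    centering: str = "diploid",
    wgd_threshold: float = 3.0,
) -> PloidyCall:
    """Average-ploidy fit and WGD flag for one sample.

    Each segment's (logR, BAF bands) is converted to implied allele-specific
    copy numbers; the fit score is the length-weighted mean squared distance
    of those to the nearest non-negative integers.  Under diploid-centered
    logR the total copy number is identified directly (2 * 2^logR) and
    psi_hat is the grid value nearest the length-weighted mean total; under
    median-centered logR the total is psi * 2^logR and psi is grid-searched,
    preferring the smaller psi at near-ties.  wgd_flag is true when
    psi_hat >= ``wgd_threshold``.
    """
    if centering not in ("diploid", "median"):
        raise ValueError("centering must be 'diploid' or 'median'")
    if not segments:
        raise ValueError("no segments")
    lengths = np.array([s.segment.length for s in segments], dtype=float)
    if lengths.sum() < 0.5 * genome.total_length:
        raise ValueError(
            "segments cover < 50% of the genome; ploidy fit unreliable"
        )
    logr = np.array([s.mean_logr for s in segments])
    bsplit = np.array([_allele_split(s.baf_bands) for s in segments])
    w = lengths / lengths.sum()

    def score(total: np.ndarray) -> float:
        major = total * bsplit
        minor = total * (1.0 - bsplit)
        d = (major - np.round(major)) ** 2 + (minor - np.round(minor)) ** 2
        return float(np.sum(w * d))

    lo, hi, step = psi_grid
    grid = np.arange(lo, hi + step / 2, step)
    if centering == "diploid":
        total = 2.0 * 2.0**logr
        mean_total = float(np.sum(w * total))
        psi_hat = float(grid[np.argmin(np.abs(grid - mean_total))])
        fit = score(total)
    else:
        scores = np.array([score(psi * 2.0**logr) for psi in grid])
        best = float(scores.min())
        # prefer the smallest psi among near-ties
        psi_hat = float(grid[np.argmax(scores <= best + 1e-6)])
        fit = best
    return PloidyCall(psi_hat=psi_hat, wgd_flag=psi_hat >= wgd_threshold,
                      fit_score=fit)


# ---------------------------------------------------------------------------
# cross-sample event matrix


def _chrom_sort_key(genome: GenomeBuild | None):
    if genome is not None:
        order = {n: i for i, n in enumerate(genome.names)}
        return lambda chrom: (order.get(chrom, len(order)), chrom)

    def natural(chrom: str):
        m = re.match(r"^(chr)?(\d+|[XYM]+)$", chrom)
        if m and m.group(2).isdigit():
            return (0, int(m.group(2)), chrom)
        return (1, 0, chrom)

    return natural


def build_event_matrix(
    per_sample_events: dict[str, list[tuple[CNAEvent, float]]],
    match_overlap: float = 0.8,
    genome: GenomeBuild | None = None,
) -> EventMatrix:
    """Unify per-sample events into the event x sample MCF matrix.

    Events from different samples are the same alteration when their kinds
    match and their segments reciprocally overlap by >= ``match_overlap``
    (wgd matches wgd by kind alone); the unified segment is the
    intersection.  MCF of an event absent in a sample is 0.0.  Rows are
    ordered by genome position, with the genome-wide wgd row first.
    """
    if not per_sample_events:
        raise ValueError("need at least one sample")
    samples = list(per_sample_events)
    rows: list[dict] = []  # kind, segment (None for wgd), mcf per sample
    for sample in samples:
        for ev, f in per_sample_events[sample]:
            hit = None
            for row in rows:
                if row["kind"] != ev.kind:
                    continue
                if ev.kind == "wgd":
                    hit = row
                    break
                assert ev.segment is not None
                if reciprocal_overlap(row["segment"], ev.segment) >= match_overlap:
                    hit = row
                    break
            if hit is None:
                rows.append({
                    "kind": ev.kind,
                    "segment": ev.segment,
                    "delta": ev.copy_delta,
                    "mcf": {sample: f},
                })
            else:
                if ev.kind != "wgd":
                    hit["segment"] = hit["segment"].intersection(ev.segment)
                hit["mcf"].setdefault(sample, f)

    key = _chrom_sort_key(genome)

    def row_key(row: dict):
        if row["kind"] == "wgd":
            return (0, (), 0, 0, "")
        seg = row["segment"]
        return (1, key(seg.chrom), seg.start, seg.end, row["kind"])

    rows.sort(key=row_key)
    events: list[CNAEvent] = []
    mcf = np.zeros((len(rows), len(samples)))
    for i, row in enumerate(rows):
        ev = CNAEvent(
            event_id=f"ev{i}", kind=row["kind"],
            segment=row["segment"] if row["kind"] != "wgd" else None,
            copy_delta=row["delta"],
        )
        events.append(ev)
        for j, sample in enumerate(samples):
            f = row["mcf"].get(sample, 0.0)
            mcf[i, j] = 0.0 if not np.isfinite(f) else min(max(f, 0.0), 1.0)
    return EventMatrix(events, samples, mcf)


def refine_event_matrix(
    matrix: EventMatrix,
    signals: dict[str, "ProbeSignal"],
    thresholds: CallThresholds | None = None,
    reference_ploidy: "dict[str, float] | float" = 2.0,
) -> EventMatrix:
    """Targeted re-genotyping of absent matrix cells.

    Segment boundaries are found independently per sample, so the same
    alteration can fail the reciprocal-overlap match in a sample where a
    neighbouring subclonal event shifted its breakpoints — leaving a
    spurious 0.  For every (event, sample) cell at 0, the event's unified
    segment is re-measured directly on that sample's probes; if the local
    state passes the calling thresholds with the same kind, the estimated
    MCF replaces the 0.  True absences stay 0: the re-call applies the
    same thresholds and clone-size floor as the primary pass.
    """
    th = thresholds or CallThresholds()
    out = matrix.mcf.copy()
    sigma = {s: estimate_baf_noise(sig) for s, sig in signals.items()}
    if not isinstance(reference_ploidy, dict):
        reference_ploidy = {s: float(reference_ploidy) for s in signals}
    for i, ev in enumerate(matrix.events):
        if ev.kind not in ("gain", "loss", "cnloh") or ev.segment is None:
            continue
        seg = ev.segment
        for j, sample in enumerate(matrix.samples):
            if not (np.isfinite(out[i, j]) and out[i, j] == 0.0):
                continue
            sig = signals.get(sample)
            if sig is None or seg.chrom not in sig.positions:
                continue
            pos = sig.positions[seg.chrom]
            a, b = np.searchsorted(pos, [seg.start, seg.end])
            if b - a < 2:
                continue
            het = sig.het[seg.chrom][a:b]
            local = CalledSegment(
                segment=seg,
                mean_logr=float(np.mean(sig.logr[seg.chrom][a:b])),
                baf_bands=fit_baf_bands(sig.baf[seg.chrom][a:b][het],
                                        sigma[sample]),
                n_probes=int(b - a),
                n_het=int(het.sum()),
                sample_id=sample,
            )
            ref = reference_ploidy.get(sample, th.reference_ploidy)
            if _classify(local, th, ref) != ev.kind:
                continue
            local.call = ev.kind
            f = estimate_mcf(local, ref, th.min_het_probes)
            if f > th.clone_size_floor:
                out[i, j] = f
    return EventMatrix(list(matrix.events), list(matrix.samples), out)


def call_sample(
    signal: ProbeSignal,
    thresholds: CallThresholds | None = None,
    min_probes: int = 10,
    alpha: float = 0.01,
    merge_tol: float = 0.1,
) -> tuple[list[CalledSegment], list[tuple[CNAEvent, float]]]:
    """Segment one sample and call its events in one step."""
    segments = segment_signal(signal, min_probes=min_probes, alpha=alpha,
                              merge_tol=merge_tol)
    events = call_events(segments, thresholds)
    return segments, events
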
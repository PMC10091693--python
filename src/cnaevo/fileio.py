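"""On-disk formats: segment TSV, event-matrix TSV, newick/JSON trees,
fishplot JSON, comparison TSV, genome TSV, and the run configuration.

All TSV coordinates are 1-based inclusive (SNP-array supplementary-table
convention); the shift to the internal 0-based half-open convention happens
here and only here.  Segment files follow the supplementary-spreadsheet
dialect: a header with at least sample / chrom / start / end / call
(case-insensitive), any extra columns preserved as opaque annotations.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .arrays import ProbeSignal
from .calling import CalledSegment, CallThresholds
from .genome import CNAEvent, GenomeBuild, GenomicSegment
from .matrix import EventMatrix, parse_row_label
from .phylo import SubcloneTree
from .stats import FishplotData, GroupComparison

__all__ = [
    "load_genome_tsv",
    "write_genome_tsv",
    "read_segment_file",
    "write_segment_file",
    "segments_to_events",
    "read_event_matrix",
    "write_event_matrix",
    "write_probe_signal",
    "read_probe_signal",
    "tree_to_newick",
    "tree_to_dict",
    "fishplot_to_dict",
    "clone_truth_to_dict",
    "write_clone_truth",
    "read_clone_truth",
    "comparisons_to_frame",
    "RunConfig",
]

logger = logging.getLogger(__name__)

REQUIRED_SEGMENT_COLUMNS = ("sample", "chrom", "start", "end", "call")


def load_genome_tsv(path: str | Path) -> GenomeBuild:
    """Two-column TSV (name, length in bp), no header required."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (name, length)")
    return GenomeBuild.from_pairs(
        (str(r[0]), int(r[1])) for r in df.itertuples(index=False)
    )


def write_genome_tsv(genome: GenomeBuild, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# segment files (supplementary-table dialect)


def read_segment_file(path: str | Path) -> dict[str, list[CalledSegment]]:
    """Read a segment TSV into per-sample :class:`CalledSegment` lists.

    Coordinates are converted from 1-based inclusive to internal 0-based
    half-open.  Unknown columns land in ``annotations``; rows with call
    ``complex`` are loaded and flagged (they are annotated, never placed in
    trees).  Raises a parse error naming the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        logger.warning("%s: header-only segment file, no rows", path)
        return {}
    extra = [c for c in df.columns
             if c not in REQUIRED_SEGMENT_COLUMNS
             and c not in ("mean_logr", "mcf", "n_probes")]
    out: dict[str, list[CalledSegment]] = {}
    for i, row in df.iterrows():
        where = f"{path} row {i + 2}"  # 1-based, after header
        try:
            start = int(float(row["start"]))
            end = int(float(row["end"]))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{where}: non-numeric coordinates") from exc
        if start > end:
            raise ValueError(f"{where}: start {start} > end {end}")
        call = str(row["call"]).strip().lower()
        mean_logr = float(row["mean_logr"]) if "mean_logr" in df.columns \
            and pd.notna(row["mean_logr"]) else 0.0
        mcf = float(row["mcf"]) if "mcf" in df.columns \
            and pd.notna(row["mcf"]) else None
        n_probes = int(float(row["n_probes"])) if "n_probes" in df.columns \
            and pd.notna(row["n_probes"]) else 0
        seg = CalledSegment(
            segment=GenomicSegment(str(row["chrom"]), start - 1, end),
            mean_logr=mean_logr,
            baf_bands=(0.5,),
            n_probes=n_probes,
            call=call,
            mcf=mcf,
            sample_id=str(row["sample"]),
            annotations={c: row[c] for c in extra if pd.notna(row[c])},
        )
        out.setdefault(seg.sample_id, []).append(seg)
    return out


def write_segment_file(
    segments_by_sample: dict[str, list[CalledSegment]], path: str | Path
) -> None:
    rows = []
    for sample, segs in segments_by_sample.items():
        for s in segs:
            rows.append({
                "sample": sample,
                "chrom": s.segment.chrom,
                "start": s.segment.start + 1,
                "end": s.segment.end,
                "call": s.call,
                "mean_logr": f"{s.mean_logr:.6g}",
                "mcf": "" if s.mcf is None else f"{s.mcf:.6g}",
                "n_probes": s.n_probes,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def segments_to_events(
    segments_by_sample: dict[str, list[CalledSegment]]
) -> dict[str, list[tuple[CNAEvent, float]]]:
    """Turn file-loaded, already-called segments into per-sample event
    lists for :func:`cnaevo.calling.build_event_matrix`."""
    out: dict[str, list[tuple[CNAEvent, float]]] = {}
    for sample, segs in segments_by_sample.items():
        events: list[tuple[CNAEvent, float]] = []
        for i, s in enumerate(segs):
            if s.call in ("neutral", ""):
                continue
            if s.call == "wgd":
                ev = CNAEvent(f"{sample}:wgd", "wgd")
                events.append((ev, 1.0 if s.mcf is None else s.mcf))
                continue
            delta = {"gain": 1, "loss": -1}.get(s.call, 0)
            ev = CNAEvent(f"{sample}:{i}", s.call, s.segment, delta)
            events.append((ev, float("nan") if s.mcf is None else s.mcf))
        out[sample] = events
    return out


# ---------------------------------------------------------------------------
# event matrix TSV


def write_event_matrix(matrix: EventMatrix, path: str | Path) -> None:
    """Rows ``chrom:start-end:kind`` x sample columns; an empty cell is an
    absent event (MCF 0), ``NA`` a missing observation."""
    df = matrix.to_frame().copy()

    def fmt(v: float) -> str:
        if not np.isfinite(v):
            return "NA"
        if v == 0.0:
            return ""
        return f"{v:.9g}"

    df = df.map(fmt)
    df.index.name = "event"
    df.to_csv(path, sep="\t")


def read_event_matrix(path: str | Path) -> EventMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False)
    events = [parse_row_label(lab, f"ev{i}") for i, lab in enumerate(df.index)]
    mcf = np.zeros(df.shape)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = df.iat[i, j].strip()
            if cell == "":
                mcf[i, j] = 0.0
            elif cell.upper() == "NA":
                mcf[i, j] = np.nan
            else:
                mcf[i, j] = float(cell)
    return EventMatrix(events, [str(c) for c in df.columns], mcf)


# ---------------------------------------------------------------------------
# probe signal TSV


def write_probe_signal(signal: ProbeSignal, path: str | Path) -> None:
    rows = []
    for chrom in signal.chroms:
        pos = signal.positions[chrom]
        for k in range(len(pos)):
            rows.append((chrom, int(pos[k]) + 1, signal.logr[chrom][k],
                         signal.baf[chrom][k], int(signal.het[chrom][k])))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "logr", "baf", "het"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_probe_signal(path: str | Path, sample_id: str | None = None) -> ProbeSignal:
    df = pd.read_csv(path, sep="\t")
    positions, logr, baf, het = {}, {}, {}, {}
    for chrom, g in df.groupby("chrom", sort=False):
        positions[str(chrom)] = g["pos"].to_numpy(dtype=np.int64) - 1
        logr[str(chrom)] = g["logr"].to_numpy(dtype=float)
        baf[str(chrom)] = g["baf"].to_numpy(dtype=float)
        het[str(chrom)] = (
            g["het"].to_numpy(dtype=int).astype(bool)
            if "het" in g.columns else np.ones(len(g), dtype=bool)
        )
    return ProbeSignal(sample_id or Path(path).stem, positions, logr, baf, het)


# ---------------------------------------------------------------------------
# tree, fishplot and comparison exports


def _event_label(ev: CNAEvent) -> str:
    return ev.label or ev.event_id


def tree_to_newick(tree: SubcloneTree) -> str:
    """Newick with node-id labels and ``[&events=...]`` branch comments."""

    def render(node_id: str) -> str:
        kids = tree.children(node_id)
        inner = ""
        if kids:
            inner = "(" + ",".join(render(k.node_id) for k in kids) + ")"
        node = tree.node(node_id)
        comment = ""
        if node.events:
            comment = "[&events=" + "|".join(_event_label(e) for e in node.events) + "]"
        return f"{inner}{node_id}{comment}"

    return render("root") + ";"


def tree_to_dict(tree: SubcloneTree) -> dict:
    return {
        "samples": tree.samples,
        "tau": tree.tau,
        "nodes": [
            {
                "node_id": n.node_id,
                "parent_id": n.parent_id,
                "events": [e.event_id for e in n.events],
                "event_labels": [_event_label(e) for e in n.events],
                "profile": [float(v) for v in n.profile],
            }
            for n in tree.nodes
        ],
        "unplaced": [e.event_id for e in tree.unplaced],
    }


def fishplot_to_dict(fp: FishplotData) -> dict:
    return {
        "timepoints": fp.timepoints,
        "nodes": [
            {
                "node_id": n,
                "parent_id": fp.parents[n],
                "cumulative": [float(v) for v in fp.cumulative[n]],
                "own": [float(v) for v in fp.own[n]],
                "emergence": fp.emergence[n],
            }
            for n in fp.nodes
        ],
        "interp_passages": [int(p) for p in fp.interp_passages],
        "interp_cumulative": {
            n: [float(v) for v in fp.interp_cumulative[n]] for n in fp.nodes
        },
    }


def comparisons_to_frame(results: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "group1": r.group1, "group2": r.group2,
            "n1": r.n1, "n2": r.n2, "W": r.w,
            "p_raw": r.p_two_sided, "p_holm": r.p_holm,
            "exact": r.exact_flag,
        }
        for r in results
    ])


# ---------------------------------------------------------------------------
# simulated ground truth (tree + fractions) as JSON


def _event_to_dict(ev: CNAEvent) -> dict:
    d: dict = {"event_id": ev.event_id, "kind": ev.kind,
               "copy_delta": ev.copy_delta, "label": ev.label}
    if ev.segment is not None:
        d["chrom"] = ev.segment.chrom
        d["start"] = ev.segment.start
        d["end"] = ev.segment.end
    return d


def _event_from_dict(d: dict) -> CNAEvent:
    seg = None
    if "chrom" in d:
        seg = GenomicSegment(d["chrom"], int(d["start"]), int(d["end"]))
    return CNAEvent(d["event_id"], d["kind"], seg, int(d["copy_delta"]),
                    d.get("label", ""))


def clone_truth_to_dict(truth) -> dict:
    return {
        "genome": [[n, l] for n, l in truth.genome.chromosomes],
        "clones": [
            {"clone_id": c.clone_id, "parent_id": c.parent_id,
             "new_events": list(c.new_events), "fitness": c.fitness}
            for c in truth.clones
        ],
        "events": [_event_to_dict(e) for e in truth.events.values()],
        "event_haplotype": dict(truth.event_haplotype),
        "fractions": {
            str(p): fr for p, fr in sorted(truth.fractions.items())
        },
        "sampled_passages": list(truth.sampled_passages),
    }


def write_clone_truth(truth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(clone_truth_to_dict(truth), fh, indent=2)


def read_clone_truth(path: str | Path):
    from .simulate import Clone, CloneTruth

    with open(path) as fh:
        d = json.load(fh)
    return CloneTruth(
        genome=GenomeBuild.from_pairs(tuple((n, l) for n, l in d["genome"])),
        clones=[Clone(c["clone_id"], c["parent_id"],
                      tuple(c["new_events"]), c["fitness"])
                for c in d["clones"]],
        events={e["event_id"]: _event_from_dict(e) for e in d["events"]},
        event_haplotype={k: int(v) for k, v in d["event_haplotype"].items()},
        fractions={int(p): fr for p, fr in d["fractions"].items()},
        sampled_passages=tuple(d["sampled_passages"]),
    )


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Effective configuration of a full pipeline run.

    Every stage parameter has a recorded default; the resolved config is
    serialized next to the outputs so any run is reproducible from config +
    seed alone.
    """

    regimes: tuple[str, ...] = ("WT-like", "RB1-like", "CDKN2A-like", "TP53-like")
    seed: int = 0
    genome_tsv: str | None = None       # None -> bundled default build
    n_passages_wt: int = 45
    n_passages_ko: int = 24
    bottleneck_size: int = 1000
    event_size_dist: tuple[float, float] = (50_000.0, 50_000_000.0)
    probe_spacing: int = 50_000
    het_fraction: float = 0.3
    noise: tuple[float, float] = (0.15, 0.03)
    centering: str = "diploid"
    min_probes: int = 10
    alpha: float = 0.01
    merge_tol: float = 0.1
    thresholds: CallThresholds = field(default_factory=CallThresholds)
    match_overlap: float = 0.8
    tau: float = 0.10
    min_event_len: int = 1_000_000

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = json.load(fh)
        if "thresholds" in payload:
            payload["thresholds"] = CallThresholds(**payload["thresholds"])
        for key in ("regimes", "event_size_dist", "noise"):
            if key in payload and isinstance(payload[key], list):
                payload[key] = tuple(payload[key])
        return cls(**payload)


def environment_versions() -> dict[str, str]:
    import numpy
    import pandas
    import scipy

    return {
        "python": platform.python_version(),
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }
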
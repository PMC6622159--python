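"""End-to-end orchestration: contacts reports and coupling evaluation.

A :class:`RunConfig` collects every knob of a run (structure, coupling
source, contact methods, cutoff mode, chain separation, ranking depth,
seed, output directory).  :func:`run_contacts` produces the structural
comparison (contact maps per method, pairwise overlaps, distance
correlations, effective cutoffs) and :func:`run_eval` the coupling
evaluation (PPV at the top L/2, average precision, orientation
enrichment among top couplings).  All outputs are plain text with fixed
float formatting, so identical configurations yield byte-identical
reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import alignment_io, coupling_scores, evaluation, orientation, structure_io
from .contact_geometry import (
    DEFAULT_MIN_SEP,
    ContactMap,
    ReferenceMethod,
    contacts_fixed,
    contacts_matched,
    distance_correlation,
    distance_matrix,
    eligible_pairs,
    write_contacts,
)

__all__ = ["RunConfig", "run_contacts", "run_eval"]

ALL_METHODS = tuple(ReferenceMethod)

#: fixed-cutoff defaults per method (Å): 8 for CA, near-median matched
#: cutoffs for CB / side-chain centers, and a heavy-atom distance for
#: the minimum-distance methods
FIXED_CUTOFFS = {
    ReferenceMethod.CA: 8.0,
    ReferenceMethod.CB: 7.6,
    ReferenceMethod.SC_CENTER: 7.5,
    ReferenceMethod.MIN_ALL: 4.5,
    ReferenceMethod.MIN_SC: 4.5,
}


@dataclass
class RunConfig:
    structure: str | Path | None = None
    chain: str | None = None
    alignment: str | Path | None = None
    coupling_matrix: str | Path | None = None
    methods: tuple[ReferenceMethod, ...] = ALL_METHODS
    cutoffs: dict = field(default_factory=lambda: dict(FIXED_CUTOFFS))
    cutoff_mode: str = "matched"  # "matched" | "fixed"
    min_sep: int = DEFAULT_MIN_SEP
    k_fraction: float = 0.5  # ranking depth as a fraction of L
    map_nonstandard: bool = True
    reweight: bool = True
    identity_threshold: float = 0.8
    pseudocount: float = 0.5
    seed: int = 0
    output_dir: str | Path | None = None

    def __post_init__(self):
        self.methods = tuple(ReferenceMethod(m) for m in self.methods)
        if self.cutoff_mode not in ("matched", "fixed"):
            raise ValueError("cutoff_mode must be 'matched' or 'fixed'")


def _round(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, ndigits) for v in obj]
    return obj


def _write_json(report: dict, path: Path) -> None:
    path.write_text(json.dumps(_round(report), indent=2, sort_keys=True) + "\n")


def _load_structure(cfg: RunConfig) -> structure_io.ProteinStructure:
    if cfg.structure is None:
        raise ValueError("RunConfig.structure is required")
    return structure_io.load_structure(
        cfg.structure, chain=cfg.chain, map_nonstandard=cfg.map_nonstandard
    )


def _contact_maps(cfg: RunConfig, s) -> tuple[dict, dict, dict]:
    """Per-method distance matrices, contact maps and effective cutoffs."""
    dms = {m: distance_matrix(s, m) for m in cfg.methods}
    maps: dict[ReferenceMethod, ContactMap] = {}
    cutoffs: dict[ReferenceMethod, float] = {}
    if cfg.cutoff_mode == "matched":
        dm_ca = dms.get(ReferenceMethod.CA) or distance_matrix(s, ReferenceMethod.CA)
        n = len(contacts_fixed(dm_ca, cfg.cutoffs[ReferenceMethod.CA], cfg.min_sep).pairs)
        if n == 0:
            raise ValueError("no CA contacts at the reference cutoff; nothing to match")
        for m, dm in dms.items():
            if m is ReferenceMethod.CA:
                maps[m] = contacts_fixed(dm, cfg.cutoffs[m], cfg.min_sep)
                cutoffs[m] = cfg.cutoffs[m]
            else:
                res = contacts_matched(dm, n, cfg.min_sep)
                maps[m] = res.contact_map
                cutoffs[m] = res.effective_cutoff
    else:
        for m, dm in dms.items():
            maps[m] = contacts_fixed(dm, cfg.cutoffs[m], cfg.min_sep)
            cutoffs[m] = cfg.cutoffs[m]
    return dms, maps, cutoffs


def run_contacts(cfg: RunConfig) -> dict:
    """Contact maps under each method plus overlap/correlation report."""
    s = _load_structure(cfg)
    dms, maps, cutoffs = _contact_maps(cfg, s)
    report: dict = {
        "seed": cfg.seed,
        "chain": s.chain_id,
        "L": s.L,
        "min_sep": cfg.min_sep,
        "cutoff_mode": cfg.cutoff_mode,
        "methods": {},
        "overlaps": {},
        "distance_spearman": {},
    }
    for m in cfg.methods:
        report["methods"][m.value] = {
            "cutoff": cutoffs[m],
            "n_contacts": len(maps[m].pairs),
        }
    for a in cfg.methods:
        for b in cfg.methods:
            if a.value >= b.value:
                continue
            key = f"{a.value}|{b.value}"
            report["distance_spearman"][key] = distance_correlation(dms[a], dms[b], cfg.min_sep)
            if len(maps[a].pairs) == len(maps[b].pairs):
                from .contact_geometry import overlap_fraction
                report["overlaps"][key] = overlap_fraction(maps[a], maps[b])
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for m in cfg.methods:
            write_contacts(maps[m], dms[m], out / f"contacts_{m.value}.txt")
        _write_json(report, out / "contacts_report.json")
    return report


def _couplings(cfg: RunConfig, L: int) -> coupling_scores.CouplingMatrix:
    if cfg.coupling_matrix is not None:
        cm = coupling_scores.read_matrix(cfg.coupling_matrix)
    elif cfg.alignment is not None:
        aln = alignment_io.read_alignment(cfg.alignment)
        aln = alignment_io.filter_to_reference(aln)
        w = coupling_scores.sequence_weights(aln, cfg.identity_threshold) if cfg.reweight else None
        cm = coupling_scores.mi_apc(aln, cfg.pseudocount, w)
    else:
        raise ValueError("need either an alignment or a coupling matrix")
    if cm.L != L:
        raise ValueError(f"couplings are {cm.L}x{cm.L} but the structure has L={L}")
    return cm


def run_eval(cfg: RunConfig) -> dict:
    """Evaluate ranked couplings against every contact definition."""
    s = _load_structure(cfg)
    cm_scores = _couplings(cfg, s.L)
    rp = coupling_scores.rank_pairs(cm_scores, cfg.min_sep)
    _, maps, cutoffs = _contact_maps(cfg, s)
    k = int(s.L * cfg.k_fraction)
    report: dict = {
        "seed": cfg.seed,
        "L": s.L,
        "k": k,
        "min_sep": cfg.min_sep,
        "cutoff_mode": cfg.cutoff_mode,
        "methods": {},
        "orientation": {},
    }
    for m in cfg.methods:
        res = evaluation.ppv_top_k(rp, maps[m], k)
        ap = evaluation.average_precision(rp, maps[m])
        report["methods"][m.value] = {
            "cutoff": cutoffs[m],
            "n_contacts": len(maps[m].pairs),
            "ppv": res.ppv,
            "average_precision": ap,
        }
    all_pairs = eligible_pairs(s.L, cfg.min_sep)
    frac = lambda pairs: {
        t.value: f
        for t, f in orientation.orientation_summary(s, pairs).fractions.items()
    }
    report["orientation"]["all_pairs"] = frac(all_pairs)
    for m in cfg.methods:
        report["orientation"][f"contacts_{m.value}"] = frac(maps[m].pairs)
    for label, kk in (("top_0.25L", int(0.25 * s.L)), ("top_0.5L", int(0.5 * s.L)), ("top_L", s.L)):
        if kk >= 1 and kk <= len(rp):
            report["orientation"][label] = frac(rp.top(kk))
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_json(report, out / "eval_report.json")
        lines = ["method,cutoff,n_contacts,k,ppv,average_precision"]
        for m in cfg.methods:
            e = report["methods"][m.value]
            lines.append(
                f"{m.value},{e['cutoff']:.4f},{e['n_contacts']},{k},"
                f"{e['ppv']:.6f},{e['average_precision']:.6f}"
            )
        (out / "eval_report.csv").write_text("\n".join(lines) + "\n")
    return report
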
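"""SNP preselection: the four strategies and the merged low-density panel.

1. GWAS top fraction — the lowest-p 0.1% of markers per trait from the
   mixed-model association scan.
2. BayesB top fraction — the markers explaining the most genetic variance,
   ranked by V_i = 2 p_i (1 - p_i) g_i^2 / sigma2_a.
3. Sliding window — per non-overlapping 500 kb tile, the highest-MAF marker
   with call rate > 98%, plus both chromosome-end markers.
4. Gene annotation — per gene containing at least one marker, the
   highest-MAF marker.

The strategies are merged by set union with provenance flags OR-combined.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import BayesAlphabetModel, PosteriorEffects, PriorSpec
from .datatypes import GeneAnnotation, GenotypeMatrix, MarkerMap
from .gwas import GWASResult, mmra_gwas  # noqa: F401  (re-exported strategy 1)

__all__ = ["Panel", "select_top_fraction", "bayesb_train", "variance_explained",
           "sliding_window_select", "gene_select", "merge_panel", "mmra_gwas"]

PROVENANCE_FLAGS = ("gwas", "bayesb", "window", "gene")


def _flatten_ids(ids):
    """Flatten one level when given per-trait lists instead of a flat list."""
    out = []
    for item in ids:
        if isinstance(item, str):
            out.append(item)
        else:
            try:
                out.extend(str(x) for x in item)
            except TypeError:
                out.append(str(item))
    return out


@dataclass
class Panel:
    """Selected marker ids with per-strategy provenance, genome-ordered."""

    marker_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    maf: np.ndarray
    provenance: dict            # flag -> boolean array aligned with marker_id
    trait_attribution: dict = field(default_factory=dict)  # flag -> {trait: set(ids)}

    def __len__(self) -> int:
        return len(self.marker_id)

    def __post_init__(self) -> None:
        ids, counts = np.unique(self.marker_id.astype(str), return_counts=True)
        if (counts > 1).any():
            raise ValueError("panel marker ids are not unique")
        has_flag = np.zeros(len(self.marker_id), dtype=bool)
        for flag in self.provenance:
            has_flag |= self.provenance[flag]
        if len(self.marker_id) and not has_flag.all():
            raise ValueError("every panel marker needs at least one provenance flag")

    @classmethod
    def from_provenance(cls, per_strategy: dict, marker_map: MarkerMap,
                        mafs=None, trait_attribution=None) -> "Panel":
        """Union of per-strategy id collections, ordered by (chromosome, position).

        Each strategy's value may be a flat id collection or a collection of
        per-trait id lists (flattened before the union).
        """
        per_strategy = {flag: _flatten_ids(ids) for flag, ids in per_strategy.items()}
        union: set = set()
        for ids in per_strategy.values():
            union |= set(map(str, ids))
        idx = marker_map.index_of(sorted(union))
        order = np.lexsort((marker_map.position_bp[idx], marker_map.chromosome[idx]))
        idx = idx[order]
        sel_ids = marker_map.marker_id[idx]
        if mafs is None:
            maf = np.full(len(idx), np.nan)
        elif isinstance(mafs, dict):
            maf = np.array([mafs.get(str(m), np.nan) for m in sel_ids])
        else:
            maf = np.asarray(mafs, dtype=float)[idx]
        prov = {flag: np.array([str(m) in set(map(str, per_strategy.get(flag, ())))
                                for m in sel_ids], dtype=bool)
                for flag in PROVENANCE_FLAGS if flag in per_strategy}
        return cls(sel_ids, marker_map.chromosome[idx], marker_map.position_bp[idx],
                   maf, prov, trait_attribution or {})

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "marker_id": self.marker_id.astype(str),
            "chromosome": self.chromosome,
            "position_bp": self.position_bp,
            "maf": self.maf,
        })
        for flag in PROVENANCE_FLAGS:
            if flag in self.provenance:
                df[flag] = self.provenance[flag].astype(int)
        return df


def select_top_fraction(scores, marker_map: MarkerMap, fraction: float = 0.001,
                        order: str = "smallest") -> np.ndarray:
    """The ceil(fraction * n) markers with the most extreme scores.

    ``order`` is "smallest" (e.g. p-values) or "largest" (e.g. variance
    explained).  Ties are broken by (chromosome, position, id) so the
    selection is deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    if len(scores) != len(marker_map):
        raise ValueError("scores length does not match marker map")
    k = math.ceil(fraction * len(scores))
    key = scores if order == "smallest" else -scores
    order_idx = np.lexsort((marker_map.marker_id.astype(str),
                            marker_map.position_bp, marker_map.chromosome, key))
    return marker_map.marker_id[order_idx[:k]]


def variance_explained(effects, mafs, sigma2_a: float, squared: bool = True
                       ) -> np.ndarray:
    """Per-SNP share of additive variance, V_i = 2 p_i (1-p_i) g_i^2 / sigma2_a.

    ``squared=False`` reproduces the linear-in-g variant some reports print;
    the squared form is the variance identity and is the default.
    """
    effects = np.asarray(effects, dtype=float)
    mafs = np.asarray(mafs, dtype=float)
    if effects.shape != mafs.shape:
        raise ValueError("effects and mafs lengths differ")
    if sigma2_a <= 0:
        raise ValueError("sigma2_a must be positive")
    g_term = effects ** 2 if squared else np.abs(effects)
    return 2.0 * mafs * (1.0 - mafs) * g_term / sigma2_a


def bayesb_train(genotypes: GenotypeMatrix, y, fixed_design,
                 prior: PriorSpec | None = None, sigma2_a: float | None = None,
                 marker_map: MarkerMap | None = None) -> PosteriorEffects:
    """BayesB Gibbs run for variance-explained ranking (strategy 2)."""
    if prior is None:
        prior = PriorSpec(pi=0.999)
    model = BayesAlphabetModel(
        y, genotypes.values.astype(float), X=fixed_design, method="B",
        prior=prior, sigma2_a=sigma2_a,
        marker_ids=None if marker_map is None else marker_map.marker_id)
    return model.fit()


def sliding_window_select(marker_map: MarkerMap, mafs, call_rates=None,
                          window_bp: int = 500_000,
                          call_rate_min: float = 0.98) -> np.ndarray:
    """Highest-MAF qualified marker per non-overlapping 500 kb tile.

    Tiles start at position 1 on each chromosome.  Markers must exceed the
    call-rate threshold to qualify inside a tile; the first and last mapped
    marker of every chromosome are always included regardless.  Ties go to
    the lowest position.
    """
    mafs = np.asarray(mafs, dtype=float)
    call_rates = (np.ones(len(marker_map)) if call_rates is None
                  else np.asarray(call_rates, dtype=float))
    chosen: list = []
    for c in np.unique(marker_map.chromosome):
        idx = np.flatnonzero(marker_map.chromosome == c)
        if idx.size == 0:
            continue
        idx = idx[np.argsort(marker_map.position_bp[idx])]
        pos = marker_map.position_bp[idx]
        chosen.append(marker_map.marker_id[idx[0]])
        chosen.append(marker_map.marker_id[idx[-1]])
        tile = (pos - 1) // window_bp
        for t in np.unique(tile):
            members = idx[tile == t]
            ok = call_rates[members] > call_rate_min
            members = members[ok]
            if members.size == 0:
                continue
            # max MAF, ties -> lowest position
            best = members[np.lexsort((marker_map.position_bp[members],
                                       -mafs[members]))[0]]
            chosen.append(marker_map.marker_id[best])
    seen, out = set(), []
    for m in chosen:
        if m not in seen:
            seen.add(m)
            out.append(m)
    return np.asarray(out, dtype=object)


def gene_select(marker_map: MarkerMap, mafs, annotation: GeneAnnotation
                ) -> tuple[np.ndarray, int]:
    """Highest-MAF marker per gene with >= 1 marker; also counts empty genes.

    A marker at 1-based position p belongs to the 0-based half-open gene
    interval [s, e) iff s < p <= e.  Returns (selected ids, n_genes_without_marker).
    """
    mafs = np.asarray(mafs, dtype=float)
    chosen: list = []
    n_empty = 0
    for g in range(len(annotation)):
        on = np.flatnonzero(
            (marker_map.chromosome == annotation.chromosome[g])
            & (annotation.start_bp[g] < marker_map.position_bp)
            & (marker_map.position_bp <= annotation.end_bp[g]))
        if on.size == 0:
            n_empty += 1
            continue
        best = on[np.lexsort((marker_map.position_bp[on], -mafs[on]))[0]]
        chosen.append(marker_map.marker_id[best])
    seen, out = set(), []
    for m in chosen:
        if m not in seen:
            seen.add(m)
            out.append(m)
    return np.asarray(out, dtype=object), n_empty


def merge_panel(per_strategy: dict, marker_map: MarkerMap, mafs=None,
                trait_attribution=None) -> Panel:
    """Union the per-strategy id lists into the final deduplicated panel."""
    flat = {flag: _flatten_ids(ids) for flag, ids in per_strategy.items()}
    known = set(map(str, marker_map.marker_id))
    for flag, ids in flat.items():
        unknown = [m for m in ids if m not in known]
        if unknown:
            raise KeyError(f"strategy {flag!r} contains unknown ids: {unknown[:5]}")
    return Panel.from_provenance(flat, marker_map, mafs=mafs,
                                 trait_attribution=trait_attribution)
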
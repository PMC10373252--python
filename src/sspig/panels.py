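"""GWAS-preselected SNP panels: Top40k, ChipPlusSign, TopSign.

Windows tile each chromosome as half-open 55-kb intervals [0, 55k),
[55k, 110k), ... anchored at position 0.  Top40k keeps the lowest-p marker
per window regardless of significance; ChipPlusSign adds to the chip, per
window, the single lowest-p variant at p <= 1e-6; TopSign keeps only those
windowed significant variants.  Ties in p are broken by lower bp position,
then marker id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwas import GWASResult
from .simdata import MarkerMap

DEFAULT_WINDOW_BP = 55_000
DEFAULT_P_THRESHOLD = 1e-6

CHIP = "chip"
GWAS_TOP = "gwas_top"
GWAS_SIGNIFICANT = "gwas_significant"


@dataclass
class SNPPanel:
    name: str
    marker_ids: np.ndarray
    provenance: dict  # marker -> chip | gwas_top | gwas_significant

    @property
    def n(self) -> int:
        return len(self.marker_ids)

    def __contains__(self, marker) -> bool:
        return marker in self.provenance


def _scan_frame(gwas: GWASResult, marker_map: MarkerMap, window_bp: int) -> pd.DataFrame:
    mm = pd.DataFrame(
        {
            "marker": marker_map.marker_id,
            "chrom": marker_map.chromosome,
            "pos": marker_map.position_bp,
        }
    )
    df = mm.merge(gwas.table[["marker", "p_value"]], on="marker", how="inner")
    if df.empty:
        raise ValueError("GWAS covers none of the mapped markers")
    df["window"] = df["pos"] // window_bp
    return df


def _lowest_p_per_window(df: pd.DataFrame) -> pd.DataFrame:
    df = df.sort_values(["p_value", "pos", "marker"], kind="stable")
    return df.groupby(["chrom", "window"], as_index=False).first()


def select_top40k(
    gwas: GWASResult, marker_map: MarkerMap, window_bp: int = DEFAULT_WINDOW_BP
) -> SNPPanel:
    """Lowest-p marker in each consecutive non-overlapping window containing
    at least one tested marker (not necessarily significant)."""
    df = _scan_frame(gwas, marker_map, window_bp)
    best = _lowest_p_per_window(df)
    best = best.sort_values(["chrom", "pos"])
    ids = best["marker"].to_numpy()
    return SNPPanel("top40k", ids, {m: GWAS_TOP for m in ids})


def select_chip_plus_sign(
    gwas: GWASResult,
    chip: SNPPanel,
    marker_map: MarkerMap,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> SNPPanel:
    """Chip markers plus, per window, the lowest-p variant at
    p <= ``p_threshold``; a significant variant already on the chip is not
    duplicated."""
    df = _scan_frame(gwas, marker_map, window_bp)
    sig = df[df["p_value"] <= p_threshold]
    prov = {m: CHIP for m in chip.marker_ids}
    if not sig.empty:
        best = _lowest_p_per_window(sig)
        for m in best["marker"]:
            prov.setdefault(m, GWAS_SIGNIFICANT)
    ids = _map_ordered(marker_map, prov)
    return SNPPanel("chip_plus_sign", ids, prov)


def select_top_sign(
    gwas: GWASResult,
    marker_map: MarkerMap,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> SNPPanel:
    """Only the windowed significant variants — no chip backbone.  May be
    empty, in which case a warning is emitted and downstream scenarios should
    skip it."""
    df = _scan_frame(gwas, marker_map, window_bp)
    sig = df[df["p_value"] <= p_threshold]
    if sig.empty:
        warnings.warn("no significant variants: TopSign panel is empty")
        return SNPPanel("top_sign", np.array([], dtype=object), {})
    best = _lowest_p_per_window(sig).sort_values(["chrom", "pos"])
    ids = best["marker"].to_numpy()
    return SNPPanel("top_sign", ids, {m: GWAS_SIGNIFICANT for m in ids})


def chip_panel(marker_map: MarkerMap) -> SNPPanel:
    ids = marker_map.marker_id[marker_map.is_chip]
    return SNPPanel("chip", ids, {m: CHIP for m in ids})


def _map_ordered(marker_map: MarkerMap, prov: dict) -> np.ndarray:
    order = {m: k for k, m in enumerate(marker_map.marker_id)}
    return np.array(sorted(prov, key=lambda m: order.get(m, len(order))), dtype=object)


def combine_panels(
    panels: list[SNPPanel], name: str, marker_map: MarkerMap | None = None
) -> SNPPanel:
    """Set union of per-trait panels (multi-trait models combine the
    preselected variants of their member traits); chip provenance wins on
    conflict.  Order follows the marker map when given, else first
    appearance."""
    prov: dict = {}
    for p in panels:
        for m in p.marker_ids:
            tag = p.provenance[m]
            if m not in prov or tag == CHIP:
                prov[m] = tag
    if marker_map is not None:
        ids = _map_ordered(marker_map, prov)
    else:
        seen = dict.fromkeys(m for p in panels for m in p.marker_ids)
        ids = np.array(list(seen), dtype=object)
    return SNPPanel(name, ids, prov)
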
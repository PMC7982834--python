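"""Selection signatures: EHH, integrated EHH and the cross-population XP-EHH.

EHH at offset x from a core SNP is the probability that two randomly drawn
haplotypes carrying the same core allele are identical over the whole
interval between the core and x: sum_h C(n_h, 2) / C(n_c, 2) over the
distinct extended haplotypes h among the n_c carriers. Curves are computed
marker-by-marker outward in both directions, stopping at the chromosome end
or once EHH falls below a floor (default 0.05, which is also the integration
and haplotype-span threshold).

The site statistic iES integrates the allele-frequency-weighted combination
of the ancestral- and derived-allele EHH curves (trapezoid rule over physical
distance, restricted to the contiguous region around the core where EHH stays
at or above the floor). XP-EHH is ln(iES_cases / iES_controls), standardized
genome-wide to zero mean and unit variance; two-sided p-values come from the
standard-normal tail of the standardized statistic, computed on the log scale
so extreme scores do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import norm

from .datatypes import HaplotypePanel

EHH_FLOOR = 0.05
CANDIDATE_P = 1e-5
GENOMEWIDE_P = 1e-8


@dataclass
class EHHCurve:
    core_pos: int
    allele: int
    positions: np.ndarray  # ascending, includes core
    ehh: np.ndarray        # aligned with positions; 1.0 at the core

    @property
    def core_index(self) -> int:
        return int(np.searchsorted(self.positions, self.core_pos))


def _chrom_range(panel: HaplotypePanel, core: int) -> tuple[int, int]:
    chroms = panel.variants["chrom"].to_numpy()
    target = chroms[core]
    lo = core
    while lo > 0 and chroms[lo - 1] == target:
        lo -= 1
    hi = core
    while hi + 1 < len(chroms) and chroms[hi + 1] == target:
        hi += 1
    return lo, hi


@njit(cache=True)
def _extend_kernel(haps, carriers, core, stop, step, positions, floor):
    """Walk outward from the core, tracking the haplotype partition.

    Group labels are relabeled each step by sorting the (group, allele) keys;
    homozygosity is the within-group pair fraction.
    """
    nc = carriers.size
    denom = nc * (nc - 1) / 2.0
    group = np.zeros(nc, dtype=np.int64)
    key = np.empty(nc, dtype=np.int64)
    max_steps = abs(stop - core)
    offs = np.empty(max_steps, dtype=np.int64)
    vals = np.empty(max_steps)
    cnt = 0
    j = core
    while j != stop:
        j += step
        for i in range(nc):
            key[i] = group[i] * 2 + haps[carriers[i], j]
        order = np.argsort(key)
        gid = 0
        prev = key[order[0]]
        group[order[0]] = 0
        pairs = 0.0
        run = 1
        for t in range(1, nc):
            k2 = key[order[t]]
            if k2 != prev:
                pairs += run * (run - 1) / 2.0
                gid += 1
                run = 1
                prev = k2
            else:
                run += 1
            group[order[t]] = gid
        pairs += run * (run - 1) / 2.0
        e = pairs / denom
        offs[cnt] = positions[j]
        vals[cnt] = e
        cnt += 1
        if e < floor:
            break
    return offs[:cnt], vals[:cnt]


def _extend(haps, carriers, core, stop, step, positions, floor):
    offs, vals = _extend_kernel(
        haps, carriers, int(core), int(stop), int(step),
        np.ascontiguousarray(positions, dtype=np.int64), float(floor),
    )
    return list(offs), list(vals)


def ehh(panel: HaplotypePanel, core: int, allele: int, floor: float = EHH_FLOOR) -> EHHCurve | None:
    """EHH curve around ``core`` for carriers of ``allele``; None if < 2 carriers."""
    haps = panel.haplotypes
    carriers = np.flatnonzero(haps[:, core] == allele)
    if carriers.size < 2:
        return None
    positions = panel.variants["pos"].to_numpy()
    lo, hi = _chrom_range(panel, core)
    right = _extend(haps, carriers, core, hi, +1, positions, floor)
    left = _extend(haps, carriers, core, lo, -1, positions, floor)
    pos = np.array(left[0][::-1] + [positions[core]] + right[0])
    val = np.array(left[1][::-1] + [1.0] + right[1])
    return EHHCurve(int(positions[core]), allele, pos, val)


def integrate_ehh(curve: EHHCurve | None, floor: float = EHH_FLOOR) -> float:
    """Trapezoidal iES over the contiguous region around the core with EHH >= floor."""
    if curve is None or curve.positions.size < 2:
        return 0.0
    ok = curve.ehh >= floor
    c = curve.core_index
    lo = c
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = c
    while hi + 1 < ok.size and ok[hi + 1]:
        hi += 1
    if hi == lo:
        return 0.0
    return float(np.trapezoid(curve.ehh[lo : hi + 1], curve.positions[lo : hi + 1]))


def _site_ies(panel: HaplotypePanel, core: int, floor: float) -> float | None:
    """Allele-frequency-weighted site EHH curve, integrated."""
    haps = panel.haplotypes
    anc_allele = int(panel.ancestral[core])
    der_allele = 1 - anc_allele
    p_der = float(np.mean(haps[:, core] == der_allele))
    curves = {
        "anc": (1.0 - p_der, ehh(panel, core, anc_allele, floor)),
        "der": (p_der, ehh(panel, core, der_allele, floor)),
    }
    grid = np.unique(
        np.concatenate(
            [c.positions for _, c in curves.values() if c is not None]
            or [np.array([panel.variants["pos"].to_numpy()[core]])]
        )
    )
    combined = np.zeros_like(grid, dtype=float)
    total_w = 0.0
    for w, c in curves.values():
        if c is None:
            continue
        total_w += w
        vals = np.zeros_like(grid, dtype=float)
        idx = np.searchsorted(c.positions, grid)
        inside = (idx < c.positions.size) & (c.positions[np.minimum(idx, c.positions.size - 1)] == grid)
        vals[inside] = c.ehh[idx[inside]]
        combined += w * vals
    if total_w == 0.0:
        return None
    combined /= total_w
    core_pos = int(panel.variants["pos"].to_numpy()[core])
    return integrate_ehh(EHHCurve(core_pos, -1, grid, combined), floor)


def neglog10_p_two_sided(z: float) -> float:
    """-log10 of the two-sided standard-normal tail, log-scale (no underflow)."""
    if not np.isfinite(z):
        raise ValueError("statistic must be finite")
    log_p = np.log(2.0) + norm.logsf(abs(z))
    return float(max(-log_p / np.log(10.0), 0.0))


def xpehh_scan(
    cases: HaplotypePanel,
    controls: HaplotypePanel,
    floor: float = EHH_FLOOR,
    candidate_p: float = CANDIDATE_P,
    genomewide_p: float = GENOMEWIDE_P,
) -> pd.DataFrame:
    """Per-SNP XP-EHH between case and control panels on the same variant grid."""
    if not cases.variants[["chrom", "pos"]].equals(controls.variants[["chrom", "pos"]]):
        raise ValueError("case and control panels must share the variant grid")
    m = cases.n_variants
    ies_a = np.full(m, np.nan)
    ies_b = np.full(m, np.nan)
    for j in range(m):
        a = _site_ies(cases, j, floor)
        b = _site_ies(controls, j, floor)
        ies_a[j] = np.nan if a is None else a
        ies_b[j] = np.nan if b is None else b
    raw = np.full(m, np.nan)
    ok = (ies_a > 0) & (ies_b > 0)
    raw[ok] = np.log(ies_a[ok] / ies_b[ok])
    mu, sd = np.nanmean(raw[ok]), np.nanstd(raw[ok])
    std = np.full(m, np.nan)
    if sd > 0:
        std[ok] = (raw[ok] - mu) / sd
    neglog = np.full(m, np.nan)
    if sd > 0:
        neglog[ok] = [neglog10_p_two_sided(z) for z in std[ok]]
    out = cases.variants[["chrom", "pos"]].copy()
    out["iES_cases"] = ies_a
    out["iES_controls"] = ies_b
    out["raw"] = raw
    out["xpehh"] = std
    out["neglog10_p"] = neglog
    out["tier"] = _tiers(neglog, candidate_p, genomewide_p)
    return out


def _tiers(neglog: np.ndarray, candidate_p: float, genomewide_p: float) -> np.ndarray:
    tier = np.full(neglog.shape, "none", dtype=object)
    with np.errstate(invalid="ignore"):
        tier[neglog >= -np.log10(candidate_p)] = "candidate"
        tier[neglog >= -np.log10(genomewide_p)] = "genome-wide"
    tier[~np.isfinite(neglog)] = "none"
    return tier


def classify_hits(
    results: pd.DataFrame,
    candidate_p: float = CANDIDATE_P,
    genomewide_p: float = GENOMEWIDE_P,
) -> pd.DataFrame:
    """Rows at or beyond the candidate threshold, sorted by -log10 p descending."""
    res = results.copy()
    res["tier"] = _tiers(res["neglog10_p"].to_numpy(), candidate_p, genomewide_p)
    hits = res[res["tier"] != "none"]
    return hits.sort_values("neglog10_p", ascending=False).reset_index(drop=True)


def calc_haplen(
    panel: HaplotypePanel, core: int, allele: int, threshold: float = EHH_FLOOR
) -> tuple[int, int] | None:
    """Outermost positions (start, end) where EHH >= threshold around the core."""
    curve = ehh(panel, core, allele, floor=min(threshold, EHH_FLOOR))
    if curve is None:
        return None
    ok = curve.ehh >= threshold
    c = curve.core_index
    lo = c
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = c
    while hi + 1 < ok.size and ok[hi + 1]:
        hi += 1
    return int(curve.positions[lo]), int(curve.positions[hi])


def haplotype_spans(
    cases: HaplotypePanel, controls: HaplotypePanel, core: int, threshold: float = EHH_FLOOR
) -> pd.DataFrame:
    """Ancestral/derived haplotype spans in each population around a core SNP."""
    anc = int(cases.ancestral[core])
    rows = []
    for pop, panel in (("cases", cases), ("controls", controls)):
        for name, allele in (("ancestral", anc), ("derived", 1 - anc)):
            span = calc_haplen(panel, core, allele, threshold)
            rows.append(
                {"population": pop, "allele": name,
                 "start": span[0] if span else np.nan,
                 "end": span[1] if span else np.nan}
            )
    return pd.DataFrame(rows)
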
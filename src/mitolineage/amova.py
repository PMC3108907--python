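"""Hierarchical analysis of molecular variance (AMOVA) with Phi statistics.

Variance in a matrix of pairwise genetic distances is partitioned across
a two-level hierarchy (subspecies/regions > populations > individuals)
following Excoffier's squared-distance formulation: the total sum of
squares is (1/N) * sum_{i<j} d_ij^2, within-group sums of squares are the
analogous quantities within each group, and level sums of squares follow
by subtraction.  Variance components sigma2_a (among regions), sigma2_b
(among populations within regions) and sigma2_c (within populations) are
solved from the expected mean squares with unequal-sample-size
coefficients, and fixation-index analogues are

    Phi_RT = sigma2_a / sigma2_T
    Phi_PR = sigma2_b / (sigma2_b + sigma2_c)
    Phi_PT = (sigma2_a + sigma2_b) / sigma2_T

Significance comes from non-parametric permutation: Phi_PT permutes
individuals among populations, Phi_PR permutes individuals among
populations within their region, Phi_RT permutes whole populations among
regions.  p = (1 + #{perm >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import DistanceMatrix
from .io import SampleTable

__all__ = [
    "AmovaResult",
    "amova",
    "phi_from_components",
    "permutation_test",
    "pairwise_phi_pt",
]


@dataclass
class AmovaResult:
    df: dict[str, int]  # keys: among_regions, among_pops, within_pops
    ss: dict[str, float]
    ms: dict[str, float]
    sigma2: dict[str, float]  # a, b, c (raw, possibly negative)
    sigma2_floored: dict[str, float]  # components floored at 0
    percent: dict[str, float]
    phi: dict[str, float]  # phi_rt, phi_pr, phi_pt from raw components
    phi_floored: dict[str, float]
    p_values: dict[str, float] | None = None
    n_perm: int | None = None
    seed: int | None = None
    flags: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        levels = ["among_regions", "among_pops", "within_pops"]
        comp = {"among_regions": "a", "among_pops": "b", "within_pops": "c"}
        stat = {"among_regions": "phi_rt", "among_pops": "phi_pr", "within_pops": "phi_pt"}
        rows = []
        for lv in levels:
            rows.append(
                {
                    "source": lv,
                    "df": self.df[lv],
                    "SS": self.ss[lv],
                    "MS": self.ms[lv],
                    "variance": self.sigma2[comp[lv]],
                    "variance_floored": self.sigma2_floored[comp[lv]],
                    "percent": self.percent[comp[lv]],
                    "phi": stat[lv],
                    "phi_value": self.phi[stat[lv]],
                    "phi_value_floored": self.phi_floored[stat[lv]],
                    "p": (self.p_values or {}).get(stat[lv], float("nan")),
                }
            )
        rows.append(
            {
                "source": "total",
                "df": sum(self.df.values()),
                "SS": sum(self.ss.values()),
                "MS": float("nan"),
                "variance": sum(self.sigma2.values()),
                "variance_floored": sum(self.sigma2_floored.values()),
                "percent": 100.0,
                "phi": "",
                "phi_value": float("nan"),
                "phi_value_floored": float("nan"),
                "p": float("nan"),
            }
        )
        return pd.DataFrame(rows)


def _ss_within(d2: np.ndarray, idx: np.ndarray) -> float:
    """(1/n) * sum_{i<j in idx} d2 for one group."""
    sub = d2[np.ix_(idx, idx)]
    return float(np.triu(sub, k=1).sum() / len(idx))


def _components(
    d2: np.ndarray, pop_codes: np.ndarray, region_of_pop: np.ndarray
) -> tuple[dict, dict, dict, tuple[str, ...]]:
    """Sums of squares, df and variance components for one labelling.

    pop_codes: per-individual population index (0..P-1);
    region_of_pop: per-population region index (0..G-1).
    """
    N = len(pop_codes)
    pops = np.unique(pop_codes)
    P = len(pops)
    region_codes = region_of_pop[pop_codes]
    regions = np.unique(region_codes)
    G = len(regions)
    flags: list[str] = []

    all_idx = np.arange(N)
    ss_total = _ss_within(d2, all_idx)
    ss_wp = sum(_ss_within(d2, all_idx[pop_codes == p]) for p in pops)
    ss_wg = sum(_ss_within(d2, all_idx[region_codes == g]) for g in regions)
    ss_ap = ss_wg - ss_wp  # among populations within regions
    ss_ag = ss_total - ss_wg  # among regions

    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    ss = {"among_regions": ss_ag, "among_pops": ss_ap, "within_pops": ss_wp}
    df = {"among_regions": df_ag, "among_pops": df_ap, "within_pops": df_wp}
    ms = {k: (ss[k] / df[k] if df[k] > 0 else float("nan")) for k in ss}

    n_p = np.array([(pop_codes == p).sum() for p in pops], dtype=float)
    n_g = np.array([(region_codes == g).sum() for g in regions], dtype=float)
    sum_np2_over_ng = sum(
        (n_p[region_of_pop[pops] == g] ** 2).sum() / n_g[gi]
        for gi, g in enumerate(regions)
    )
    n1 = (N - sum_np2_over_ng) / df_ap if df_ap > 0 else float("nan")
    n2 = (sum_np2_over_ng - (n_p**2).sum() / N) / df_ag if df_ag > 0 else float("nan")
    n3 = (N - (n_g**2).sum() / N) / df_ag if df_ag > 0 else float("nan")

    s2c = ms["within_pops"]
    s2b = (ms["among_pops"] - s2c) / n1 if df_ap > 0 else 0.0
    if df_ag > 0:
        s2a = (ms["among_regions"] - s2c - n2 * s2b) / n3
    else:
        s2a = float("nan")
        flags.append("single_region_phi_rt_undefined")
    sigma2 = {"a": s2a, "b": s2b, "c": s2c}
    return ss, df, ms, sigma2, tuple(flags)


def phi_from_components(s2a: float, s2b: float, s2c: float) -> dict[str, float]:
    """Phi statistics from the three variance components.

    A NaN s2a (single-region design) leaves phi_rt undefined; the other
    statistics are computed with the among-region component absent.
    """
    if np.isnan(s2a):
        return {
            "phi_rt": float("nan"),
            "phi_pr": s2b / (s2b + s2c),
            "phi_pt": s2b / (s2b + s2c),
        }
    total = s2a + s2b + s2c
    return {
        "phi_rt": s2a / total,
        "phi_pr": s2b / (s2b + s2c),
        "phi_pt": (s2a + s2b) / total,
    }


def _codes(dm: DistanceMatrix, groups: SampleTable) -> tuple[np.ndarray, np.ndarray, list[str]]:
    groups_idx = groups.rows.set_index("sample")
    pops = sorted(groups.rows["population"].unique())
    pop_index = {p: i for i, p in enumerate(pops)}
    regions = sorted(groups.rows["subspecies"].unique())
    region_index = {r: i for i, r in enumerate(regions)}
    pop_codes = np.array(
        [pop_index[groups_idx.loc[s, "population"]] for s in dm.labels]
    )
    region_of_pop = np.array(
        [region_index[groups.subspecies_of_population(p)] for p in pops]
    )
    return pop_codes, region_of_pop, pops


def amova(dm: DistanceMatrix, groups: SampleTable) -> AmovaResult:
    """Two-level hierarchical AMOVA on a distance matrix.

    Distances enter squared.  Raw (possibly negative) variance components
    are reported alongside components floored at zero, with Phi computed
    from both; negative components are flagged, never silently truncated.
    """
    missing = set(dm.labels) - set(groups.samples)
    if missing:
        raise ValueError(f"samples without group labels: {sorted(missing)}")
    pop_codes, region_of_pop, _ = _codes(dm, groups)
    d2 = dm.d**2
    ss, df, ms, sigma2, flags = _components(d2, pop_codes, region_of_pop)
    flags = list(flags)
    if any(v < 0 for v in sigma2.values() if not np.isnan(v)):
        flags.append("negative_variance_component")
    floored = {k: (v if np.isnan(v) else max(v, 0.0)) for k, v in sigma2.items()}
    total = float(np.nansum(list(sigma2.values())))
    percent = {k: 100.0 * v / total for k, v in sigma2.items()}
    phi = phi_from_components(sigma2["a"], sigma2["b"], sigma2["c"])
    phi_fl = phi_from_components(floored["a"], floored["b"], floored["c"])
    return AmovaResult(
        df=df,
        ss=ss,
        ms=ms,
        sigma2=sigma2,
        sigma2_floored=floored,
        percent=percent,
        phi=phi,
        phi_floored=phi_fl,
        flags=tuple(flags),
    )


def _phi_stat(d2, pop_codes, region_of_pop, which: str) -> float:
    _, _, _, sigma2, _ = _components(d2, pop_codes, region_of_pop)
    return phi_from_components(sigma2["a"], sigma2["b"], sigma2["c"])[which]


def permutation_test(
    dm: DistanceMatrix,
    groups: SampleTable,
    statistic: str,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> float:
    """Permutation p-value for one Phi statistic.

    Permutation schemes follow the statistic's null: phi_pt shuffles
    individuals among populations; phi_pr shuffles individuals among
    populations within their region; phi_rt reassigns whole populations
    to regions.
    """
    statistic = statistic.lower()
    if statistic not in ("phi_rt", "phi_pr", "phi_pt"):
        raise ValueError("statistic must be phi_rt, phi_pr or phi_pt")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pop_codes, region_of_pop, pops = _codes(dm, groups)
    if len(pops) < 2:
        raise ValueError("permutation test undefined for a single group")
    d2 = dm.d**2
    rng = np.random.default_rng(seed)
    observed = _phi_stat(d2, pop_codes, region_of_pop, statistic)
    region_codes = region_of_pop[pop_codes]
    exceed = 0
    for _ in range(n_perm):
        if statistic == "phi_pt":
            perm_pops = rng.permutation(pop_codes)
            stat = _phi_stat(d2, perm_pops, region_of_pop, statistic)
        elif statistic == "phi_pr":
            perm_pops = pop_codes.copy()
            for g in np.unique(region_codes):
                mask = region_codes == g
                perm_pops[mask] = rng.permutation(pop_codes[mask])
            stat = _phi_stat(d2, perm_pops, region_of_pop, statistic)
        else:  # phi_rt: move whole populations among regions
            perm_region_of_pop = rng.permutation(region_of_pop)
            stat = _phi_stat(d2, pop_codes, perm_region_of_pop, statistic)
        if stat >= observed - 1e-12:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def _one_level_phi(d2: np.ndarray, codes: np.ndarray) -> float:
    """Phi_PT for a one-level (populations only) design."""
    N = len(codes)
    pops = np.unique(codes)
    P = len(pops)
    all_idx = np.arange(N)
    ss_total = _ss_within(d2, all_idx)
    ss_wp = sum(_ss_within(d2, all_idx[codes == p]) for p in pops)
    ss_ap = ss_total - ss_wp
    df_ap, df_wp = P - 1, N - P
    ms_ap = ss_ap / df_ap
    s2c = ss_wp / df_wp if df_wp > 0 else 0.0
    n_p = np.array([(codes == p).sum() for p in pops], dtype=float)
    n0 = (N - (n_p**2).sum() / N) / df_ap
    s2a = (ms_ap - s2c) / n0
    denom = s2a + s2c
    if denom == 0:
        return 0.0
    return s2a / denom


def pairwise_phi_pt(
    dm: DistanceMatrix,
    groups: SampleTable,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Population-pair Phi_PT matrix: Phi below the diagonal, p above.

    Each pair of populations is analysed as a one-level AMOVA; a pair of
    identical monomorphic populations has Phi reported as 0 (undefined
    0/0, flagged by NaN p).
    """
    pops = sorted(groups.rows["population"].unique())
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(np.nan, index=pops, columns=pops)
    for i, pa in enumerate(pops):
        for j in range(i + 1, len(pops)):
            pb = pops[j]
            keep = [
                s
                for s in dm.labels
                if groups.population_of(s) in (pa, pb)
            ]
            sub = dm.submatrix(keep)
            codes = np.array(
                [0 if groups.population_of(s) == pa else 1 for s in keep]
            )
            d2 = sub.d**2
            if np.allclose(d2, 0):
                out.iloc[j, i] = 0.0  # identical monomorphic pair, flagged via NaN p
                continue
            observed = _one_level_phi(d2, codes)
            exceed = 0
            for _ in range(n_perm):
                stat = _one_level_phi(d2, rng.permutation(codes))
                if stat >= observed - 1e-12:
                    exceed += 1
            out.iloc[j, i] = observed
            out.iloc[i, j] = (1 + exceed) / (1 + n_perm)
    return out
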
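"""Cross-species conservation, discordance and turnover of generation bias,
plus term-enrichment and summary statistics.

Each single-copy orthogroup carries one bias state per species (GA, SP,
unbiased, or missing).  Across the full species set (ASOs) an orthogroup is
*discordant* when it holds both a GA-biased and an SP-biased member, and
*shared-k* when exactly k species are biased toward the same generation with
no opposite-direction member (missing species never block sharing).  Within
a species pair (PSOs) the categories are conserved-GA / conserved-SP /
discordant / gain-loss (biased in exactly one species) / unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

BIAS_STATES = ("GA", "SP", "unbiased", "missing")


@dataclass(frozen=True)
class AsoConservationCall:
    orthogroup: str
    states: tuple[str, ...]
    category: str  # "unbiased" | "shared-k-GA" | "shared-k-SP" | "discordant"


@dataclass(frozen=True)
class PsoPairCall:
    orthogroup: str
    states: tuple[str, str]
    category: str  # "conserved-GA" | "conserved-SP" | "discordant" | "gain-loss" | "unbiased"


def _check_states(states, allow_missing=True):
    allowed = set(BIAS_STATES) if allow_missing else set(BIAS_STATES) - {"missing"}
    bad = set(states) - allowed
    if bad:
        raise ValueError(f"unknown bias states: {sorted(bad)}")


def classify_aso(orthogroup: str, states: dict[str, str]) -> AsoConservationCall:
    """Conservation category of one ASO from its per-species bias states."""
    vals = tuple(states.values())
    _check_states(vals)
    n_ga = vals.count("GA")
    n_sp = vals.count("SP")
    if vals.count("missing") > 1:
        raise ValueError(f"{orthogroup}: ASOs have at most one missing species")
    if n_ga and n_sp:
        cat = "discordant"
    elif n_ga:
        cat = f"shared-{n_ga}-GA"
    elif n_sp:
        cat = f"shared-{n_sp}-SP"
    else:
        cat = "unbiased"
    return AsoConservationCall(orthogroup=orthogroup, states=vals, category=cat)


def classify_pso(orthogroup: str, state1: str, state2: str) -> PsoPairCall:
    """Pairwise category of one PSO (both members present by definition)."""
    _check_states((state1, state2), allow_missing=False)
    biased1 = state1 in ("GA", "SP")
    biased2 = state2 in ("GA", "SP")
    if biased1 and biased2:
        cat = f"conserved-{state1}" if state1 == state2 else "discordant"
    elif biased1 or biased2:
        cat = "gain-loss"
    else:
        cat = "unbiased"
    return PsoPairCall(orthogroup=orthogroup, states=(state1, state2), category=cat)


def bias_state_table(
    calls_by_species: dict[str, pd.DataFrame],
    omap,
    orthogroups: list[str],
    species: list[str] | None = None,
) -> pd.DataFrame:
    """Per-orthogroup per-species bias state for single-copy members.

    A species is ``missing`` when the orthogroup has no gene there; a member
    classified not-expressed counts as unbiased for conservation purposes.
    ``species`` restricts the table to a subset (e.g. a PSO pair, where the
    other species may hold several copies).
    """
    if species is None:
        species = omap.species
    rows = {}
    for og in orthogroups:
        members = omap.groups[og]
        row = {}
        for sp in species:
            genes = members[sp]
            if not genes:
                row[sp] = "missing"
                continue
            if len(genes) > 1:
                raise ValueError(f"{og}: species {sp} has {len(genes)} members; not single-copy")
            cls = calls_by_species[sp].loc[genes[0], "class"]
            row[sp] = {"GA-biased": "GA", "SP-biased": "SP"}.get(cls, "unbiased")
        rows[og] = row
    return pd.DataFrame.from_dict(rows, orient="index")[species]


def classify_aso_table(states: pd.DataFrame) -> pd.Series:
    return pd.Series(
        {og: classify_aso(og, row.to_dict()).category for og, row in states.iterrows()},
        name="category",
        dtype=object,
    )


def classify_pso_table(states: pd.DataFrame, pair: tuple[str, str]) -> pd.Series:
    return pd.Series(
        {og: classify_pso(og, row[pair[0]], row[pair[1]]).category for og, row in states.iterrows()},
        name="category",
        dtype=object,
    )


def fisher_enrichment(
    target: set[str],
    background: set[str],
    annotations: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided (enrichment) hypergeometric test per term.

    ``annotations`` has columns ``gene_id`` and ``term_id`` (optionally
    ``term_name``).  Terms with no annotated gene in the background are
    skipped.  Reports the raw p (cutoff column at ``alpha``) alongside a BH
    column.
    """
    if not target or not background:
        raise ValueError("target and background must be non-empty")
    if not target <= background:
        raise ValueError("target must be a subset of background")
    ann = annotations[annotations["gene_id"].isin(background)]
    M, N = len(background), len(target)
    rows = []
    for term, sub in ann.groupby("term_id"):
        genes = set(sub["gene_id"])
        n = len(genes)
        k = len(genes & target)
        p = float(stats.hypergeom.sf(k - 1, M, n, N))
        table = np.array([[k, n - k], [N - k, M - n - (N - k)]])
        odds = stats.contingency.odds_ratio(table, kind="sample").statistic if table.min() >= 0 else np.nan
        name = sub["term_name"].iloc[0] if "term_name" in sub else ""
        rows.append({"term_id": term, "term_name": name, "n_term": n, "n_hit": k, "odds_ratio": odds, "pvalue": p})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    from .biascall import bh_adjust

    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    out["significant"] = out["pvalue"] < alpha
    return out.sort_values("pvalue").reset_index(drop=True)


def chisq_gof(observed: list[int], expected: list[float] | None = None) -> dict:
    """Pearson chi-squared goodness-of-fit (equal expectation by default)."""
    obs = np.asarray(observed, dtype=float)
    if expected is None:
        expected = np.full_like(obs, obs.sum() / obs.size)
    chi2, p = stats.chisquare(obs, expected)
    return {"chi2": float(chi2), "df": int(obs.size - 1), "pvalue": float(p)}


def ranksum_contrast(x, y) -> dict:
    """Two-sided Wilcoxon rank-sum contrast; skipped for degenerate groups."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        return {"skipped": True, "note": "group with <2 members"}
    res = stats.ranksums(x, y)
    return {"skipped": False, "statistic": float(res.statistic), "pvalue": float(res.pvalue),
            "mean_x": float(x.mean()), "mean_y": float(y.mean())}


def venn_counts(biased_ogs_by_species: dict[str, set[str]]) -> dict[str, int]:
    """Counts of orthogroups with >=1 biased gene shared across every
    species subset (keys are '+'-joined sorted species names)."""
    from itertools import combinations

    out = {}
    species = sorted(biased_ogs_by_species)
    for r in range(1, len(species) + 1):
        for combo in combinations(species, r):
            shared = set.intersection(*(biased_ogs_by_species[s] for s in combo))
            out["+".join(combo)] = len(shared)
    return out


def summary_report(
    calls_by_species: dict[str, pd.DataFrame],
    aso_categories: pd.Series | None = None,
    floor_by_species: dict[str, float] | None = None,
) -> dict:
    """Headline per-species and cross-species summary tables.

    Per species: biased proportions among expressed genes and the
    generation-specific fraction among biased genes; across species: the
    ASO category tally when provided.
    """
    per_species = {}
    for sp, calls in calls_by_species.items():
        expressed = calls[calls["class"] != "not-expressed"]
        n = len(expressed)
        ga = (expressed["class"] == "GA-biased").sum()
        spb = (expressed["class"] == "SP-biased").sum()
        spec_ga = int((expressed["specific"] & (expressed["class"] == "GA-biased")).sum())
        spec_sp = int((expressed["specific"] & (expressed["class"] == "SP-biased")).sum())
        per_species[sp] = {
            "n_expressed": int(n),
            "prop_GA_biased": float(ga / n) if n else float("nan"),
            "prop_SP_biased": float(spb / n) if n else float("nan"),
            "prop_biased": float((ga + spb) / n) if n else float("nan"),
            "specific_frac_GA": float(spec_ga / ga) if ga else float("nan"),
            "specific_frac_SP": float(spec_sp / spb) if spb else float("nan"),
        }
    report = {"per_species": per_species}
    if aso_categories is not None:
        tally = aso_categories.value_counts().to_dict()
        n_aso = int(len(aso_categories))
        n_biased = int(sum(v for k, v in tally.items() if k != "unbiased"))
        report["aso"] = {
            "n": n_aso,
            "n_with_bias": n_biased,
            "frac_with_bias": n_biased / n_aso if n_aso else float("nan"),
            "n_discordant": int(tally.get("discordant", 0)),
            "frac_discordant_of_biased": (tally.get("discordant", 0) / n_biased) if n_biased else float("nan"),
            "categories": {k: int(v) for k, v in tally.items()},
        }
    if floor_by_species:
        report["floors"] = {k: float(v) for k, v in floor_by_species.items()}
    return report
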
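"""Risk of non-adaptedness (RONA).

For each environmentally associated locus, population allele frequency
is regressed on the current value of the variable; the per-locus RONA
of a population is the absolute difference between the fitted
frequency under future and current climate, |slope| * |delta env|. The
population-level RONA per variable averages the per-locus values
weighted by the regression R^2. Variables are ranked by their number
of significant loci and the top three flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..envtable import EnvTable
from ..genotypes import GenotypeMatrix


@dataclass
class RonaResult:
    rona: pd.DataFrame  # populations x variables (weighted average)
    per_locus: pd.DataFrame  # rows: (variable, locus) with slope, intercept, r2, mean RONA
    weights: pd.DataFrame  # normalized R^2 weight per (variable, locus)
    sig_counts: pd.Series  # significant-locus count per variable
    top_variables: list[str]


def rona(
    g: GenotypeMatrix,
    env: EnvTable,
    future_env: EnvTable,
    sig_loci: dict[str, list[str]],
    top_n: int = 3,
) -> RonaResult:
    """Weighted RONA per population and variable.

    ``env``/``future_env`` are population-level tables (rows aligned to
    the population order of ``g``); ``sig_loci`` maps each variable to
    the locus ids significantly associated with it. Variables with no
    significant loci are excluded with a warning.
    """
    pop_freq = g.population_frequencies()
    pops = list(pop_freq.index)
    if env.sites != pops or future_env.sites != pops:
        raise ValueError("env tables must be aligned to the population order")

    usable = {v: ids for v, ids in sig_loci.items() if ids}
    dropped = [v for v in sig_loci if not sig_loci[v]]
    if dropped:
        warnings.warn(f"variables with no significant loci excluded: {dropped}")
    if not usable:
        raise ValueError("no variable has significant loci")

    rona_cols = {}
    rows = []
    weight_rows = []
    for var, ids in usable.items():
        e_cur = env.data[var].to_numpy(float)
        e_fut = future_env.data[var].to_numpy(float)
        delta = e_fut - e_cur
        per_locus_rona = []
        r2s = []
        for lid in ids:
            f = pop_freq[lid].to_numpy(float)
            ok = ~np.isnan(f)
            slope, intercept = np.polyfit(e_cur[ok], f[ok], 1)
            fitted = slope * e_cur + intercept
            ss_res = ((f[ok] - fitted[ok]) ** 2).sum()
            ss_tot = ((f[ok] - f[ok].mean()) ** 2).sum()
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
            r2 = max(r2, 0.0)
            locus_rona = np.abs(slope) * np.abs(delta)
            per_locus_rona.append(locus_rona)
            r2s.append(r2)
            rows.append(
                {
                    "variable": var,
                    "locus": lid,
                    "slope": slope,
                    "intercept": intercept,
                    "r2": r2,
                    "mean_rona": float(locus_rona.mean()),
                }
            )
        r2s = np.asarray(r2s)
        mat = np.vstack(per_locus_rona)  # (n_loci, n_pops)
        wsum = r2s.sum()
        if wsum == 0.0:
            weights = np.full(len(r2s), 1.0 / len(r2s))
        else:
            weights = r2s / wsum
        rona_cols[var] = weights @ mat
        for lid, w in zip(ids, weights):
            weight_rows.append({"variable": var, "locus": lid, "weight": float(w)})

    counts = pd.Series({v: len(ids) for v, ids in usable.items()}).sort_values(ascending=False)
    return RonaResult(
        rona=pd.DataFrame(rona_cols, index=pops),
        per_locus=pd.DataFrame(rows).set_index(["variable", "locus"]),
        weights=pd.DataFrame(weight_rows).set_index(["variable", "locus"]),
        sig_counts=counts,
        top_variables=list(counts.index[:top_n]),
    )
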
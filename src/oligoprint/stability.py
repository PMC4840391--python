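"""Temporal stability and fingerprint statistics.

For each (individual, taxon) pair over that individual's time series the mean
relative abundance, the sample standard deviation (n-1 denominator) and the
percent coefficient of variation CV = 100 * sd / mean are computed, together
with pooled all-sample aggregates per taxon.  The fingerprint contrast — a
low within-individual CV for an individual's persistently abundant oligotypes
against a much higher CV for the same oligotypes pooled across everybody —
is the core evidence that oligotype profiles are individual-specific.  A
leave-one-out nearest-centroid classifier under Bray-Curtis distance
operationalizes "individuals can be told apart" at any taxonomic level.

Conventions: statistics are computed on unrounded values and reported on the
percent scale; means are printed to 1 decimal and CVs to the nearest integer,
half away from zero.  A CV is undefined (NaN, excluded from aggregates) when
the mean is exactly 0.  With n samples and a single nonzero value the CV is
100*sqrt(n) percent — 283 for n = 8 — which pins the n-1 convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis

from ._utils import round_half_away
from .community import AbundanceTable


@dataclass
class StabilityTable:
    """Per-(individual, taxon) and per-taxon temporal statistics (percent).

    `per_individual` is indexed by (individual, taxon) with columns
    mean / sd / cv; `per_taxon` is indexed by taxon with columns
    overall_mean / overall_sd / overall_cv / mean_cv (all-sample pooled
    statistics and the unweighted mean of per-individual CVs).  All values
    are unrounded; rounding happens only in report writers.
    """

    per_individual: pd.DataFrame
    per_taxon: pd.DataFrame | None = None
    level: str = "genus"

    def cv(self, individual: str, taxon: str) -> float:
        return float(self.per_individual.loc[(individual, taxon), "cv"])

    def mean(self, individual: str, taxon: str) -> float:
        return float(self.per_individual.loc[(individual, taxon), "mean"])


def per_individual_stats(table: AbundanceTable, percent_scale: bool = True) -> StabilityTable:
    """Mean, sample SD and CV% of every taxon within every individual.

    Requires at least 2 samples per individual (an SD needs a residual
    degree of freedom).  CV is NaN where the mean is exactly 0.
    """
    scale = 100.0 if (percent_scale and table.relative) else 1.0
    individuals = table.individuals()
    counts = individuals.value_counts()
    thin = counts[counts < 2]
    if len(thin):
        raise ValueError(f"individuals with < 2 samples: {list(thin.index)}")
    rows = []
    for ind, sample_ids in individuals.groupby(individuals).groups.items():
        block = table.data.loc[list(sample_ids)] * scale
        mean = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = 100.0 * sd / mean
        cv = cv.where(mean != 0, np.nan)
        frame = pd.DataFrame({"mean": mean, "sd": sd, "cv": cv})
        frame.index = pd.MultiIndex.from_product(
            [[ind], frame.index], names=["individual", table.level]
        )
        rows.append(frame)
    return StabilityTable(per_individual=pd.concat(rows), level=table.level)


def aggregate_stats(stability: StabilityTable, table: AbundanceTable) -> StabilityTable:
    """Add per-taxon pooled aggregates and the unweighted mean of per-individual CVs.

    overall_mean / overall_cv pool all samples from all individuals; mean_cv
    averages the per-individual CVs (defined entries only), unweighted —
    the convention the printed per-row aggregates follow.
    """
    scale = 100.0 if table.relative else 1.0
    data = table.data * scale
    overall_mean = data.mean(axis=0)
    overall_sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        overall_cv = 100.0 * overall_sd / overall_mean
    overall_cv = overall_cv.where(overall_mean != 0, np.nan)
    mean_cv = stability.per_individual["cv"].groupby(level=1).mean()
    per_taxon = pd.DataFrame(
        {
            "overall_mean": overall_mean,
            "overall_sd": overall_sd,
            "overall_cv": overall_cv,
            "mean_cv": mean_cv,
        }
    )
    return StabilityTable(
        per_individual=stability.per_individual, per_taxon=per_taxon, level=stability.level
    )


def row_aggregates(
    means_by_individual: Sequence[float], cvs_by_individual: Sequence[float]
) -> tuple[float, float]:
    """Report-row aggregates from per-individual means and CVs (percent).

    With equal per-individual sample counts, the pooled overall mean equals
    the unweighted mean of the per-individual means; the row's "Mean CV" is
    the unweighted mean of the per-individual CVs.  Returns (overall mean to
    1 decimal, mean CV to nearest integer), rounded half away from zero.
    """
    overall_mean = round_half_away(float(np.mean(means_by_individual)), 1)
    mean_cv = round_half_away(float(np.mean(cvs_by_individual)))
    return overall_mean, mean_cv


def anomaly_series(table: AbundanceTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample anomaly from the individual mean, plus SD band edges.

    anomaly(sample, taxon) = abundance - that individual's temporal mean;
    anomalies of any (individual, taxon) series sum to 0.  The second frame
    holds, per (individual, taxon), the mean and the +/-1 and +/-2 SD band
    edges around it.
    """
    individuals = table.individuals()
    means = table.data.groupby(individuals).transform("mean")
    anomalies = table.data - means
    group_mean = table.data.groupby(individuals).mean()
    group_sd = table.data.groupby(individuals).std(ddof=1)
    bands = pd.concat(
        {
            "mean": group_mean,
            "lo1": group_mean - group_sd,
            "hi1": group_mean + group_sd,
            "lo2": group_mean - 2 * group_sd,
            "hi2": group_mean + 2 * group_sd,
        },
        names=["band"],
    )
    return anomalies, bands


def within_genus_profile(
    oligotype_table: AbundanceTable,
    genus_of: dict[str, str],
    genus: str,
) -> tuple[AbundanceTable, list[str]]:
    """Oligotype abundances renormalized by their genus total in each sample.

    Returns the within-genus profile table (rows sum to 1) and the list of
    samples excluded because the genus total was 0 there.
    """
    members = [t for t in oligotype_table.taxa if genus_of.get(t) == genus]
    if not members:
        raise ValueError(f"genus {genus!r} has no oligotypes in the table")
    block = oligotype_table.data[members]
    totals = block.sum(axis=1)
    excluded = list(totals.index[totals == 0])
    keep = totals.index[totals > 0]
    data = block.loc[keep].div(totals.loc[keep], axis=0)
    profile = AbundanceTable(
        data=data,
        sample_meta=oligotype_table.sample_meta.loc[keep],
        level="oligotype",
        relative=True,
    )
    return profile, excluded


def abundant_oligotypes(
    profile_stats: StabilityTable, threshold: float = 10.0
) -> tuple[set[tuple[str, str]], set[str]]:
    """(individual, oligotype) pairs whose within-individual mean is strictly
    above `threshold` percent, plus the union of oligotypes abundant in at
    least one individual."""
    means = profile_stats.per_individual["mean"]
    pairs = {tuple(ix) for ix in means.index[means > threshold]}
    union = {taxon for _, taxon in pairs}
    return pairs, union


def fingerprint_summary(
    profile_stats: StabilityTable,
    abundant_pairs: set[tuple[str, str]],
) -> tuple[float, float]:
    """The within-mouth vs everywhere CV contrast, rounded to integers.

    mean_abundant_cv: unweighted mean of within-individual CVs over the
    abundant (individual, oligotype) pairs.  mean_overall_cv: unweighted mean
    of the pooled all-sample CV over the abundant-in-anyone oligotype union.
    """
    if not abundant_pairs:
        raise ValueError("abundant set is empty")
    if profile_stats.per_taxon is None:
        raise ValueError("aggregate_stats must be applied first")
    cvs = [
        profile_stats.per_individual.loc[pair, "cv"]
        for pair in sorted(abundant_pairs)
    ]
    cvs = [c for c in cvs if not np.isnan(c)]
    union = sorted({taxon for _, taxon in abundant_pairs})
    overall = profile_stats.per_taxon.loc[union, "overall_cv"].dropna()
    mean_abundant_cv = round_half_away(float(np.mean(cvs)))
    mean_overall_cv = round_half_away(float(overall.mean()))
    return mean_abundant_cv, mean_overall_cv


def _centroid_distances(
    table: AbundanceTable, held_out_sample: str
) -> dict[str, float]:
    individuals = table.individuals()
    held = table.data.loc[held_out_sample].to_numpy()
    out: dict[str, float] = {}
    for ind in sorted(individuals.unique()):
        members = [
            s
            for s in table.samples
            if individuals[s] == ind and s != held_out_sample
        ]
        if not members:
            continue
        centroid = table.data.loc[members].mean(axis=0).to_numpy()
        out[ind] = float(braycurtis(held, centroid))
    return out


def fingerprint_classify(table: AbundanceTable, held_out_sample: str) -> str:
    """Nearest-centroid prediction of the held-out sample's individual.

    The centroid of an individual is the mean profile of its remaining
    samples (only the held-out sample's own individual loses one sample, so
    >= 2 samples per individual suffice); distance is Bray-Curtis; exact
    ties break by individual label order.
    """
    dists = _centroid_distances(table, held_out_sample)
    if not dists:
        raise ValueError("no candidate individuals")
    best = min(dists.values())
    for ind in sorted(dists):  # label order breaks exact ties
        if dists[ind] == best:
            return ind
    raise AssertionError("unreachable")


def loo_accuracy(table: AbundanceTable) -> float:
    """Leave-one-out accuracy of fingerprint_classify over all samples."""
    individuals = table.individuals()
    hits = sum(
        fingerprint_classify(table, s) == individuals[s] for s in table.samples
    )
    return hits / len(table.samples)


def write_stability_table(stability: StabilityTable, path: str | Path) -> None:
    """Write a report TSV: taxa as rows, per-individual M/CV column pairs,
    then Overall M/CV and Mean CV.  Means 1 decimal, CVs nearest integer."""
    per_ind = stability.per_individual
    individuals = sorted(per_ind.index.get_level_values(0).unique())
    taxa = list(dict.fromkeys(per_ind.index.get_level_values(1)))
    with open(path, "w") as fh:
        header = ["taxon"]
        for ind in individuals:
            header += [f"{ind}_M", f"{ind}_CV"]
        header += ["Overall_M", "Overall_CV", "Mean_CV"]
        fh.write("\t".join(header) + "\n")
        for taxon in taxa:
            row = [taxon]
            for ind in individuals:
                try:
                    m = per_ind.loc[(ind, taxon), "mean"]
                    cv = per_ind.loc[(ind, taxon), "cv"]
                except KeyError:
                    row += ["", ""]
                    continue
                row.append(f"{round_half_away(m, 1):.1f}")
                row.append("" if np.isnan(cv) else f"{round_half_away(cv):.0f}")
            if stability.per_taxon is not None and taxon in stability.per_taxon.index:
                agg = stability.per_taxon.loc[taxon]
                row.append(f"{round_half_away(agg['overall_mean'], 1):.1f}")
                for key in ("overall_cv", "mean_cv"):
                    v = agg[key]
                    row.append("" if np.isnan(v) else f"{round_half_away(v):.0f}")
            else:
                row += ["", "", ""]
            fh.write("\t".join(row) + "\n")
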
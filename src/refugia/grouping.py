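"""Cluster-number diagnostics and geo-genetic-group definition rules.

Consumes the outputs of an external Bayesian clustering run (per-K
log-likelihood traces and Q matrices of cluster proportions) and applies
the documented decision rules: the Evanno second-difference criterion
for the number of clusters, the admixture filter excluding populations
without a clear majority cluster, and the two-of-three criterion
(distinct cluster, divergent network branch, geographic isolation) that
validates a proposed group of populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class QMatrix:
    """Population (or individual) by K cluster-proportion rows."""

    def __init__(self, proportions, labels):
        self.values = np.asarray(proportions, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Q matrix must be two-dimensional")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("cluster proportions must be in [0, 1]")
        if np.any(np.abs(self.values.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("Q-matrix rows must sum to 1")
        self.labels = list(labels)
        if len(self.labels) != len(self.values):
            raise ValueError("label count does not match row count")

    @classmethod
    def from_tsv(cls, path) -> "QMatrix":
        """TSV with a label column followed by K proportion columns."""
        df = pd.read_csv(path, sep="\t", header=None)
        return cls(df.iloc[:, 1:].to_numpy(dtype=float),
                   df.iloc[:, 0].astype(str).tolist())

    def population_means(self, pop_of_row: dict[str, str]) -> "QMatrix":
        """Average individual rows into population rows."""
        pops = list(dict.fromkeys(pop_of_row[lab] for lab in self.labels))
        rows = []
        for pop in pops:
            idx = [i for i, lab in enumerate(self.labels)
                   if pop_of_row[lab] == pop]
            rows.append(self.values[idx].mean(axis=0))
        return QMatrix(np.array(rows), pops)


def evanno_delta_k(traces: dict[int, list[float]]) -> dict[int, float]:
    """Evanno's delta-K from per-K replicate log-likelihoods.

    ``deltaK(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K))``
    for interior K with both neighbours present; the boundary K values
    are undefined.  A zero replicate standard deviation yields
    ``inf`` with a warning.
    """
    import warnings

    ks = sorted(traces)
    if len(ks) < 3:
        raise ValueError("delta-K needs at least three consecutive K")
    mean = {k: float(np.mean(traces[k])) for k in ks}
    sd = {k: float(np.std(traces[k], ddof=1)) for k in ks}
    out = {}
    for k in ks[1:-1]:
        if k - 1 not in traces or k + 1 not in traces:
            raise ValueError(f"delta-K at K={k} needs K-1 and K+1 traces")
        num = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
        if sd[k] == 0:
            warnings.warn(f"sd of L(K={k}) is zero; delta-K is infinite")
            out[k] = float("inf")
        else:
            out[k] = num / sd[k]
    return out


def read_k_traces(path) -> dict[int, list[float]]:
    """TSV with columns K, replicate, logL."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["K", "replicate", "logL"])
    return {int(k): grp["logL"].tolist()
            for k, grp in df.groupby("K", sort=True)}


def admixture_filter(q: QMatrix, major_gt: float = 0.5,
                     second_lt: float = 0.35) -> tuple[list[str], list[str]]:
    """Keep populations whose major cluster proportion strictly exceeds
    ``major_gt`` and whose second-largest is strictly below ``second_lt``;
    admixed populations would blur the demographic signal.  Returns
    (kept, excluded) label lists."""
    kept, excluded = [], []
    for lab, row in zip(q.labels, q.values):
        top = np.sort(row)[::-1]
        second = top[1] if len(top) > 1 else 0.0
        if top[0] > major_gt and second < second_lt:
            kept.append(lab)
        else:
            excluded.append(lab)
    return kept, excluded


@dataclass(frozen=True)
class GroupCriteria:
    """Per-population refugium-group evidence flags: membership in a
    distinct genetic cluster, position on a divergent network branch,
    and strong geographic isolation (the last is expert judgment, hence
    caller-supplied)."""

    distinct_cluster: bool
    divergent_branch: bool
    geographically_isolated: bool

    def count(self) -> int:
        return int(self.distinct_cluster) + int(self.divergent_branch) \
            + int(self.geographically_isolated)


def assign_geo_genetic_groups(criteria: dict[str, GroupCriteria],
                              proposed_groups: dict[str, list[str]],
                              ) -> dict:
    """Validate proposed groups with the two-of-three rule.

    Every population must appear in exactly one proposed group.  A
    group's flags are the conjunction over its members (a group is only
    as distinct/divergent/isolated as its least-supported member); it is
    validated when at least two of the three hold.  Returns a report
    with validated groups and, for failing groups, the criteria that
    failed.
    """
    seen: dict[str, str] = {}
    for gname, members in proposed_groups.items():
        for pop in members:
            if pop in seen:
                raise ValueError(f"population {pop!r} in both "
                                 f"{seen[pop]!r} and {gname!r}")
            if pop not in criteria:
                raise ValueError(f"no criteria for population {pop!r}")
            seen[pop] = gname
    missing = set(criteria) - set(seen)
    if missing:
        raise ValueError(f"populations not assigned to any group: "
                         f"{sorted(missing)}")
    validated, rejected = {}, {}
    for gname, members in proposed_groups.items():
        flags = {
            "distinct_cluster": all(criteria[p].distinct_cluster
                                    for p in members),
            "divergent_branch": all(criteria[p].divergent_branch
                                    for p in members),
            "geographically_isolated": all(
                criteria[p].geographically_isolated for p in members),
        }
        n_met = sum(flags.values())
        entry = {"members": list(members), "criteria": flags,
                 "n_criteria_met": n_met}
        if n_met >= 2:
            validated[gname] = entry
        else:
            entry["failed"] = [k for k, v in flags.items() if not v]
            rejected[gname] = entry
    return {"validated": validated, "rejected": rejected}


def isolation_helper(coords: dict[str, tuple[float, float]],
                     group_of: dict[str, str],
                     threshold: float) -> dict[str, bool]:
    """Optional helper flagging populations whose nearest population
    outside their own group is farther than ``threshold`` (Euclidean in
    the supplied coordinates)."""
    out = {}
    for pop, (x, y) in coords.items():
        dists = [np.hypot(x - x2, y - y2)
                 for pop2, (x2, y2) in coords.items()
                 if pop2 != pop and group_of[pop2] != group_of[pop]]
        out[pop] = bool(dists) and bool(min(dists) > threshold)
    return out
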
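"""PITT-miR classification and the inter-tissue trafficking network.

A miRNA is *potentially inter-tissue transported* (PITT) in a tissue when it
is detected there by sequencing (expression call, E) but its promoter shows
no reporter activity there (transcription call, T).  For each miRNA and age
the source set S = {tissues with E and T} and the receiver set
R = {tissues with E and not T} define directed trafficking edges: the miRNA
is added to every (s -> r) edge with s in S, r in R.  A miRNA with
receivers but no internal source is attributed to an "Other" source outside
the modelled tissues.

Edge weights (numbers of miRNAs per direction) are tested against a
degree-preserving null: each permutation independently redraws, per miRNA,
disjoint random source and receiver sets of the observed sizes ("Other"
sources stay "Other").  The null edge-weight sample is brought towards
normality by a Yeo-Johnson power transform (maximum-likelihood lambda per
edge), the observed weight is transformed with the same lambda, and
z = (w_obs' - mean(null')) / sd(null') with a two-sided normal p-value.
An empirical rank p-value is reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import OTHER_SOURCE
from .datatypes import DetectionTable

logger = logging.getLogger("mirflux")


# ---------------------------------------------------------------------------
# E/T profiles
# ---------------------------------------------------------------------------

def expression_calls(detection: DetectionTable, tissues) -> pd.DataFrame:
    """Group-level E calls restricted to the given tissues (mature x (tissue, age))."""
    cols = [c for c in detection.per_group.columns if c[0] in tuple(tissues)]
    return detection.per_group[cols].copy()


def replicate_expression_calls(
    detection: DetectionTable, samples: pd.DataFrame, tissues
) -> dict[int, pd.DataFrame]:
    """Per-replicate E calls: replicate -> mature x (tissue, age) table."""
    out: dict[int, pd.DataFrame] = {}
    tissues = tuple(tissues)
    for rep in sorted(samples["replicate"].unique()):
        sub = samples[(samples["replicate"] == rep) & samples["tissue"].isin(tissues)]
        cols = pd.MultiIndex.from_tuples(
            [(row["tissue"], row["age"]) for _, row in sub.iterrows()],
            names=["tissue", "age"],
        )
        block = detection.per_replicate[list(sub.index)].copy()
        block.columns = cols
        out[int(rep)] = block
    return out


def align_te(
    e_calls: pd.DataFrame, t_calls: pd.DataFrame, analysable=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align E and T tables on a common mature set and column vocabulary.

    Matures present in E but missing from the transcription mapping are
    excluded with a warning (promoters that cannot be assessed); an explicit
    ``analysable`` id list restricts further.
    """
    matures = [m for m in e_calls.index if m in t_calls.index]
    dropped = [m for m in e_calls.index if m not in t_calls.index]
    if dropped:
        logger.warning(
            "%d mature miRNAs absent from the transcription map excluded: %s",
            len(dropped),
            dropped[:10],
        )
    if analysable is not None:
        analysable = set(analysable)
        matures = [m for m in matures if m in analysable]
    cols = [c for c in e_calls.columns if c in t_calls.columns]
    return e_calls.loc[matures, cols].astype(bool), t_calls.loc[matures, cols].astype(bool)


def classify_pitt(
    e_calls: pd.DataFrame, t_calls: pd.DataFrame, analysable=None
) -> tuple[set[str], pd.DataFrame]:
    """PITT calls: expressed without transcription, per (tissue, age).

    Returns the global PITT set (PITT in at least one tissue-age) and the
    boolean mature x (tissue, age) PITT table.
    """
    E, T = align_te(e_calls, t_calls, analysable)
    pitt_table = E & ~T
    pitt_set = set(pitt_table.index[pitt_table.any(axis=1)])
    logger.info(
        "PITT classification: %d/%d analysable matures are PITT in >=1 (tissue, age)",
        len(pitt_set),
        len(pitt_table),
    )
    return pitt_set, pitt_table


# ---------------------------------------------------------------------------
# trafficking network
# ---------------------------------------------------------------------------

@dataclass
class TraffickingNetwork:
    """Directed tissue->tissue miRNA trafficking network at one age."""

    age: str
    tissues: tuple[str, ...]
    #: mature -> (source tissue set, or {OTHER_SOURCE}; receiver tissue set)
    sources: dict[str, frozenset] = field(default_factory=dict)
    receivers: dict[str, frozenset] = field(default_factory=dict)
    edges: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph(age=self.age)
        for _, row in self.edges.iterrows():
            g.add_edge(
                row["source"],
                row["target"],
                weight=int(row["weight"]),
                mirnas=list(row["mirnas"]),
            )
        return g


def network_from_sets(
    sources: dict[str, frozenset],
    receivers: dict[str, frozenset],
    tissues,
    age: str,
) -> TraffickingNetwork:
    """Assemble the edge table from per-miRNA source/receiver sets.

    A miRNA with sources S and receivers R contributes to every edge of
    S x R (no fractional weights); miRNAs with an empty receiver set are
    dropped; an empty source set becomes the external "Other" source.
    """
    tissues = tuple(tissues)
    src: dict[str, frozenset] = {}
    rec: dict[str, frozenset] = {}
    edge_members: dict[tuple[str, str], list[str]] = {}
    for m, R in receivers.items():
        R = frozenset(R)
        if not R:
            continue
        S = frozenset(sources.get(m, frozenset()))
        if not S:
            S = frozenset({OTHER_SOURCE})
        if S & R:
            raise ValueError(f"{m}: source and receiver sets overlap: {S & R}")
        src[m], rec[m] = S, R
        for s in S:
            for r in R:
                edge_members.setdefault((s, r), []).append(m)
    rows = [
        {"source": s, "target": r, "weight": len(ms), "mirnas": sorted(ms)}
        for (s, r), ms in sorted(edge_members.items())
    ]
    edges = pd.DataFrame(rows, columns=["source", "target", "weight", "mirnas"])
    return TraffickingNetwork(
        age=age, tissues=tissues, sources=src, receivers=rec, edges=edges
    )


def build_trafficking_network(
    e_calls: pd.DataFrame, t_calls: pd.DataFrame, age: str, analysable=None
) -> TraffickingNetwork:
    """Construct the weighted trafficking network for one age from E/T calls."""
    E, T = align_te(e_calls, t_calls, analysable)
    tissues = tuple(dict.fromkeys(c[0] for c in E.columns))
    ecols = {t: (t, age) for t in tissues if (t, age) in E.columns}

    sources: dict[str, frozenset] = {}
    receivers: dict[str, frozenset] = {}
    for m in E.index:
        S = frozenset(t for t, c in ecols.items() if E.loc[m, c] and T.loc[m, c])
        R = frozenset(t for t, c in ecols.items() if E.loc[m, c] and not T.loc[m, c])
        sources[m], receivers[m] = S, R
    net = network_from_sets(sources, receivers, tissues, age)
    logger.info(
        "trafficking network (%s): %d transported miRNAs, %d directed edges",
        age,
        len(net.receivers),
        len(net.edges),
    )
    return net


def _null_edge_weights(
    net: TraffickingNetwork,
    n_perm: int,
    rng: np.random.Generator,
    null: str = "degree_preserving",
) -> np.ndarray:
    """Null edge-weight tensor [n_perm x (tissues + Other) x tissues].

    ``degree_preserving`` (default): per permutation and miRNA, disjoint
    S'/R' of the observed sizes are drawn uniformly from the tissue set;
    Other-source miRNAs keep their external source and only their receiver
    set is redrawn.  ``pair_shuffle``: each of a miRNA's |S|*|R| edge
    memberships is reassigned to a uniformly random ordered tissue pair
    (degrees not preserved; kept as a cruder comparison null).
    """
    tissues = list(net.tissues)
    k = len(tissues)
    n_src = k + 1  # last row = Other
    weights = np.zeros((n_perm, n_src, k), dtype=np.int32)
    rows = np.arange(n_perm)
    for m in net.sources:
        S, R = net.sources[m], net.receivers[m]
        r = len(R)
        is_other = S == frozenset({OTHER_SOURCE})
        s = 0 if is_other else len(S)
        if null == "degree_preserving":
            # random permutation of tissue indices per permutation round
            perms = np.argsort(rng.random((n_perm, k)), axis=1)
            if is_other:
                for b in range(r):
                    np.add.at(weights, (rows, np.full(n_perm, k), perms[:, b]), 1)
            else:
                for a in range(s):
                    for b in range(r):
                        np.add.at(weights, (rows, perms[:, a], perms[:, s + b]), 1)
        elif null == "pair_shuffle":
            n_members = r if is_other else s * r
            for _ in range(n_members):
                if is_other:
                    src = np.full(n_perm, k)
                    dst = rng.integers(0, k, n_perm)
                else:
                    src = rng.integers(0, k, n_perm)
                    dst = (src + rng.integers(1, k, n_perm)) % k
                np.add.at(weights, (rows, src, dst), 1)
        else:
            raise ValueError(f"unknown null model {null!r}")
    return weights


def permutation_flow_test(
    net: TraffickingNetwork,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    null: str = "degree_preserving",
) -> pd.DataFrame:
    """Permutation z and p per observed edge; returns the annotated edge table.

    Columns added: z, p_normal (two-sided from the standard normal after
    Yeo-Johnson transformation of the null), p_empirical (add-one rank),
    yj_lambda, null_mean, null_sd.  Degenerate nulls (sd 0) yield z = NaN
    and p = 1 with a log flag.
    """
    if net.edges.empty:
        return net.edges.assign(
            z=[], p_normal=[], p_empirical=[], yj_lambda=[], null_mean=[], null_sd=[]
        )
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    tissues = list(net.tissues)
    src_index = {t: i for i, t in enumerate(tissues)}
    src_index[OTHER_SOURCE] = len(tissues)
    dst_index = {t: i for i, t in enumerate(tissues)}

    null_weights = _null_edge_weights(net, n_perm, rng, null=null)

    z = np.full(len(net.edges), np.nan)
    p_norm = np.ones(len(net.edges))
    p_emp = np.ones(len(net.edges))
    lams = np.full(len(net.edges), np.nan)
    mus = np.full(len(net.edges), np.nan)
    sds = np.full(len(net.edges), np.nan)
    for i, row in enumerate(net.edges.itertuples(index=False)):
        obs = float(row.weight)
        sample = null_weights[:, src_index[row.source], dst_index[row.target]].astype(float)
        if sample.std() == 0.0:
            logger.warning(
                "degenerate permutation null for edge %s->%s; z undefined, p=1",
                row.source,
                row.target,
            )
            continue
        # Yeo-Johnson handles zero null weights (Box-Cox would not)
        transformed, lam = stats.yeojohnson(sample)
        obs_t = float(stats.yeojohnson(np.array([obs]), lmbda=lam)[0])
        mu, sd = float(transformed.mean()), float(transformed.std(ddof=0))
        if sd == 0.0:
            continue
        zi = (obs_t - mu) / sd
        z[i] = zi
        p_norm[i] = float(2.0 * min(stats.norm.cdf(zi), stats.norm.sf(zi)))
        ge = int(np.sum(sample >= obs))
        le = int(np.sum(sample <= obs))
        p_emp[i] = min(1.0, 2.0 * (1 + min(ge, le)) / (n_perm + 1))
        lams[i], mus[i], sds[i] = lam, mu, sd

    out = net.edges.copy()
    out["z"] = z
    out["p_normal"] = p_norm
    out["p_empirical"] = p_emp
    out["yj_lambda"] = lams
    out["null_mean"] = mus
    out["null_sd"] = sds
    return out


def flow_summary(
    e_by_replicate: dict[int, pd.DataFrame],
    t_calls: pd.DataFrame,
    ages,
    analysable=None,
) -> pd.DataFrame:
    """Per-tissue outgoing/incoming miRNA counts per age and replicate.

    out(t): distinct miRNAs with t among their sources and a non-empty
    receiver set; in(t): distinct miRNAs with t among their receivers.
    Emitted as a tidy table for downstream statistics.
    """
    rows = []
    for rep, e_calls in sorted(e_by_replicate.items()):
        for age in ages:
            net = build_trafficking_network(e_calls, t_calls, age, analysable)
            tissues = net.tissues
            out_counts = {t: 0 for t in tissues}
            in_counts = {t: 0 for t in tissues}
            for m in net.sources:
                for t in net.sources[m]:
                    if t != OTHER_SOURCE:
                        out_counts[t] += 1
                for t in net.receivers[m]:
                    in_counts[t] += 1
            for t in tissues:
                rows.append(
                    {
                        "tissue": t,
                        "age": age,
                        "replicate": rep,
                        "out_count": out_counts[t],
                        "in_count": in_counts[t],
                    }
                )
    return pd.DataFrame(rows, columns=["tissue", "age", "replicate", "out_count", "in_count"])
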
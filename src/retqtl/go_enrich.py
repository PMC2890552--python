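"""MAPPFinder-style Gene Ontology / gene-set overrepresentation.

For a term containing ``n`` measured genes of which ``r`` are changed, with
``N`` measured annotated genes and ``R`` changed among them, the Z score is
the standardized hypergeometric count

    z = (r - n R / N) / sqrt( n (R/N) (1 - R/N) (1 - (n-1)/(N-1)) ),

and the permutation p value comes from shuffling the changed/unchanged
labels over the measured genes. The ranked, filtered list keeps terms with
permutation p < 0.01, z >= 2, percent changed > 10 and at least 2 changed
genes, sorted by p ascending then z descending. The same machinery applies
unchanged to pathway gene sets (MAPPs).

Up-in-C and up-in-B6a gene lists are analyzed separately per age, mirroring
the four blocks of the study design; callers pass whichever changed-gene set
they need.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "z_score",
    "permutation_p",
    "enrich",
    "rank_and_filter",
    "rollup_annotations",
    "read_annotation",
]


def z_score(r: int, n: int, R: int, N: int) -> float:
    """Standardized hypergeometric overrepresentation statistic.

    Parameters are the MAPPFinder counts: r changed genes in the term, n
    measured genes in the term, R changed genes overall, N measured
    annotated genes overall. When the hypergeometric variance is zero
    (R = 0, R = N, or n = N) the statistic is defined as 0 with a warning.
    """
    if not (0 <= r <= n <= N and 0 <= R <= N):
        raise ValueError(f"invalid counts r={r} n={n} R={R} N={N}")
    if N <= 1 or R == 0 or R == N or n == N:
        logger.warning("zero-variance enrichment counts (r=%d n=%d R=%d N=%d); z := 0",
                       r, n, R, N)
        return 0.0
    p = R / N
    var = n * p * (1.0 - p) * (1.0 - (n - 1) / (N - 1))
    return (r - n * p) / math.sqrt(var)


def _z_vector(r: np.ndarray, n: np.ndarray, R: int, N: int) -> np.ndarray:
    if N <= 1 or R == 0 or R == N:
        return np.zeros(len(r))
    p = R / N
    var = n * p * (1 - p) * (1 - (n - 1) / (N - 1))
    z = np.zeros(len(r), float)
    ok = var > 0
    z[ok] = (r[ok] - n[ok] * p) / np.sqrt(var[ok])
    return z


def _term_matrix(term_genes: Mapping[str, set[str]],
                 measured: list[str]) -> tuple[list[str], np.ndarray]:
    idx = {g: i for i, g in enumerate(measured)}
    terms = sorted(term_genes)
    mat = np.zeros((len(terms), len(measured)), dtype=np.float64)
    for ti, term in enumerate(terms):
        for g in term_genes[term]:
            if g in idx:
                mat[ti, idx[g]] = 1.0
    return terms, mat


def permutation_p(term_genes: Mapping[str, set[str]], measured: Iterable[str],
                  changed: set[str], n_perm: int = 2000,
                  seed: int | None = 0) -> pd.Series:
    """Permutation p per term: P(null z >= observed z).

    Changed/unchanged labels are permuted over the measured genes and the z
    score recomputed; ``p = (1 + #{null z >= observed}) / (1 + n_perm)``, so
    p is never exactly 0. Fixed seed gives an identical p vector across runs.
    """
    if n_perm < 1000:
        raise ValueError(f"n_perm must be >= 1000 for the p < 0.01 criterion, got {n_perm}")
    measured = list(measured)
    N = len(measured)
    flags = np.array([g in changed for g in measured], dtype=bool)
    R = int(flags.sum())
    terms, mat = _term_matrix(term_genes, measured)
    n_in_term = mat.sum(axis=1)
    z_obs = _z_vector(mat @ flags.astype(float), n_in_term, R, N)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms), dtype=np.int64)
    f = flags.astype(float)
    for _ in range(n_perm):
        rng.shuffle(f)
        r_null = mat @ f
        z_null = _z_vector(r_null, n_in_term, R, N)
        exceed += z_null >= z_obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.Series(p, index=terms, name="permute_p")


def enrich(term_genes: Mapping[str, set[str]], measured: Iterable[str],
           changed: set[str], n_perm: int = 2000, seed: int | None = 0,
           term_names: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Score every term; one row per term with counts, z and permutation p.

    ``measured`` is the annotated, on-array gene universe; ``changed`` the
    regulated subset in the direction/age under analysis.
    """
    measured = list(dict.fromkeys(measured))
    changed = set(changed) & set(measured)
    N, R = len(measured), len(changed)
    terms, mat = _term_matrix(term_genes, measured)
    n_in_term = mat.sum(axis=1)
    flags = np.array([g in changed for g in measured], dtype=bool)
    r = (mat @ flags.astype(float)).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_in_term > 0, 100.0 * r / n_in_term, 0.0)
    rows = pd.DataFrame(
        {
            "term_id": terms,
            "term_name": [term_names.get(t, t) if term_names else t for t in terms],
            "n_changed": r,
            "n_measured_in_term": n_in_term.astype(int),
            "percent_changed": pct,
            "z_score": _z_vector(r, n_in_term, R, N),
        }
    ).set_index("term_id")
    rows["permute_p"] = permutation_p(term_genes, measured, changed,
                                      n_perm=n_perm, seed=seed)
    return rows


def rank_and_filter(rows: pd.DataFrame, p_max: float = 0.01, z_min: float = 2.0,
                    pct_min: float = 10.0, r_min: int = 2) -> pd.DataFrame:
    """Ranked, filtered term list.

    Keeps rows with permutation p < 0.01 AND z >= 2 AND percent changed
    strictly > 10 AND at least 2 changed genes; sorts by p ascending with
    ties broken by z descending.
    """
    keep = (
        (rows["permute_p"] < p_max)
        & (rows["z_score"] >= z_min)
        & (rows["percent_changed"] > pct_min)
        & (rows["n_changed"] >= r_min)
    )
    out = rows[keep].sort_values(["permute_p", "z_score"],
                                 ascending=[True, False])
    return out


def rollup_annotations(gene_terms: Mapping[str, set[str]],
                       parent_edges: Iterable[tuple[str, str]]) -> dict[str, set[str]]:
    """Propagate every gene's annotations to all ancestor terms.

    ``parent_edges`` are (child_term, parent_term) pairs forming a DAG
    (is_a / part_of rollup). Idempotent; a cycle raises an error. Diamond
    structures count each gene once per ancestor (set semantics).
    """
    g = nx.DiGraph()
    g.add_edges_from(parent_edges)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"term hierarchy contains a cycle: {cycle}")
    out: dict[str, set[str]] = {}
    for gene, terms in gene_terms.items():
        full = set(terms)
        for t in terms:
            if t in g:
                full |= nx.descendants(g, t)  # edges point child -> parent
        out[gene] = full
    return out


def invert_annotation(gene_terms: Mapping[str, set[str]]) -> dict[str, set[str]]:
    """gene -> terms mapping inverted to term -> genes."""
    term_genes: dict[str, set[str]] = {}
    for gene, terms in gene_terms.items():
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)
    return term_genes


def read_annotation(path) -> dict[str, set[str]]:
    """Annotation TSV (gene, term_id) -> gene -> set-of-terms mapping."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"gene", "term_id"}.issubset(df.columns):
        raise ValueError(f"{path}: annotation needs columns gene, term_id")
    out: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.gene), set()).add(str(r.term_id))
    return out
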
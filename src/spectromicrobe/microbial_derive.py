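"""Derivation of soil microbial response variables.

Two measurement streams are supported:

* **PLFA** (phospholipid fatty acid) lipid biomarkers, summed into broad
  functional groups (Gram-positive and Gram-negative bacteria,
  Actinomycetales, saprophytic fungi, arbuscular-mycorrhizal fungi) with
  the fungal:bacterial (F:B) and Gram-positive:Gram-negative (G+:G-)
  ratios.
* **16S rRNA ASV tables**: taxonomy filtering (drop Archaea and undefined
  taxa), rarefaction to a common read depth, dominant-phylum relative
  abundances, ASV richness, Bray-Curtis dissimilarities with NMDS
  ordination, plus the Hellinger and centred log-ratio (CLR)
  compositional transforms.

The F:B ratio here counts Actinomycetales in the bacterial denominator
(they are Gram-positive bacteria); membership tuples are module constants
so alternative conventions can be applied by passing custom groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.composition import clr as _skbio_clr
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .errors import DataError

logger = logging.getLogger(__name__)

# PLFA biomarker vocabulary (lipid names use ASCII 'w' for omega).
GRAM_POSITIVE = ("i14:0", "i15:0", "i16:0", "i17:0", "a15:0", "a17:0")
GRAM_NEGATIVE = ("cyclo17:0", "cyclo19:0")
ACTINOMYCETALES = ("10Me16:0", "10Me17:0", "10Me18:0")
SAPROPHYTIC_FUNGI = ("16:1w7cis", "18:2w6", "18:3w6")
AM_FUNGI = ("16:1w5",)

ALL_BIOMARKERS = GRAM_POSITIVE + GRAM_NEGATIVE + ACTINOMYCETALES + SAPROPHYTIC_FUNGI + AM_FUNGI

#: Taxonomy strings treated as "undefined" at kingdom or phylum rank.
UNDEFINED_TOKENS = frozenset({"", "na", "nan", "none", "undefined", "unclassified", "unknown"})


def plfa_groups(
    lipids: pd.DataFrame,
    sample_col: str = "sample_id",
    lipid_col: str = "lipid",
    value_col: str = "concentration_nmol_g",
) -> pd.DataFrame:
    """Sum lipid concentrations into PLFA functional groups per sample.

    ``lipids`` is a long table (sample, lipid name, concentration in
    nmol per g dry soil). Returns one row per sample with columns
    ``gram_positive, gram_negative, actinomycetes, saprophytic_fungi,
    am_fungi, total_plfa, fb_ratio, gp_gn_ratio``. ``total_plfa`` sums
    every measured biomarker. F:B = (SF + AMF) / (G+ + G- + Actino);
    ratios with a zero denominator are returned as NaN.
    """
    if (lipids[value_col] < 0).any():
        raise DataError("lipid concentrations must be non-negative")
    wide = lipids.pivot_table(
        index=sample_col, columns=lipid_col, values=value_col, aggfunc="sum"
    )
    missing = sorted(set(ALL_BIOMARKERS) - set(wide.columns))
    if missing:
        raise DataError(f"missing biomarker lipids: {', '.join(missing)}")
    if wide[list(ALL_BIOMARKERS)].isna().any().any():
        bad = sorted(wide.columns[wide[list(ALL_BIOMARKERS)].isna().any()])
        raise DataError(f"biomarker lipids absent for some samples: {', '.join(bad)}")

    out = pd.DataFrame(index=wide.index)
    out["gram_positive"] = wide[list(GRAM_POSITIVE)].sum(axis=1)
    out["gram_negative"] = wide[list(GRAM_NEGATIVE)].sum(axis=1)
    out["actinomycetes"] = wide[list(ACTINOMYCETALES)].sum(axis=1)
    out["saprophytic_fungi"] = wide[list(SAPROPHYTIC_FUNGI)].sum(axis=1)
    out["am_fungi"] = wide[list(AM_FUNGI)].sum(axis=1)
    out["total_plfa"] = wide.sum(axis=1)  # every measured biomarker
    fungi = out["saprophytic_fungi"] + out["am_fungi"]
    bacteria = out["gram_positive"] + out["gram_negative"] + out["actinomycetes"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["fb_ratio"] = np.where(bacteria > 0, fungi / bacteria, np.nan)
        out["gp_gn_ratio"] = np.where(
            out["gram_negative"] > 0, out["gram_positive"] / out["gram_negative"], np.nan
        )
    return out


def _is_undefined(label: object) -> bool:
    if label is None or (isinstance(label, float) and math.isnan(label)):
        return True
    return str(label).strip().lower() in UNDEFINED_TOKENS


def filter_taxa(
    counts: pd.DataFrame, taxonomy: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Remove ASVs assigned to Archaea or with undefined taxonomy.

    ``counts`` is samples x ASVs; ``taxonomy`` has columns
    ``asv_id, kingdom, phylum``. Returns the filtered table and the list
    of removed ASV ids. Counts of retained ASVs are untouched.
    """
    tax = taxonomy.set_index("asv_id")
    removed = []
    for asv in counts.columns:
        if asv not in tax.index:
            removed.append(asv)
            continue
        kingdom = tax.at[asv, "kingdom"]
        phylum = tax.at[asv, "phylum"]
        if _is_undefined(kingdom) or _is_undefined(phylum):
            removed.append(asv)
        elif str(kingdom).strip().lower() == "archaea":
            removed.append(asv)
    return counts.drop(columns=removed), removed


def rarefy(
    counts: pd.DataFrame, depth: int = 5000, seed: int | None = 0
) -> tuple[pd.DataFrame, list[str]]:
    """Rarefy each sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped (strictly fewer
    than ``depth``; a sample with exactly ``depth`` reads is retained
    unchanged). Subsampling is multivariate-hypergeometric, seeded for
    reproducibility. Returns the rarefied table and the dropped sample ids.
    """
    if depth < 1:
        raise DataError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    mat = counts.to_numpy()
    if not np.issubdtype(mat.dtype, np.integer):
        if not np.allclose(mat, np.round(mat)):
            raise DataError("ASV counts must be integers")
        mat = np.round(mat).astype(np.int64)
    totals = mat.sum(axis=1)
    keep = totals >= depth
    dropped = [str(s) for s, k in zip(counts.index, keep) if not k]
    if not keep.any():
        logger.warning("rarefaction dropped every sample (depth=%d)", depth)
    rows = []
    for row, total in zip(mat[keep], totals[keep]):
        if total == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth, method="marginals"))
    out = pd.DataFrame(
        np.array(rows, dtype=np.int64) if rows else np.empty((0, mat.shape[1]), dtype=np.int64),
        index=counts.index[keep],
        columns=counts.columns,
    )
    return out, dropped


def dominant_phyla(
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame,
    top_fraction: float = 0.10,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample relative abundance of the dominant phyla plus "Other".

    A phylum is dominant when it occurs in every sample *and* ranks in the
    top ``ceil(top_fraction * P)`` phyla by mean relative abundance
    (P = number of distinct phyla; ties broken by total reads, then name).
    All remaining phyla are summed into "Other". Per-sample fractions are
    raw phylum reads divided by the sample's total reads.
    """
    tax = taxonomy.set_index("asv_id")["phylum"]
    phyla = tax.reindex(counts.columns)
    phylum_counts = counts.T.groupby(phyla).sum().T  # samples x phyla
    totals = phylum_counts.sum(axis=1)
    if (totals == 0).any():
        raise DataError("samples with zero reads cannot be converted to fractions")
    rel = phylum_counts.div(totals, axis=0)

    ubiquitous = (phylum_counts > 0).all(axis=0)
    n_top = math.ceil(top_fraction * phylum_counts.shape[1])
    ranking = pd.DataFrame(
        {
            "mean_rel": rel.mean(axis=0),
            "total_reads": phylum_counts.sum(axis=0),
            "name": [str(p) for p in phylum_counts.columns],
        }
    ).sort_values(
        ["mean_rel", "total_reads", "name"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    top = set(ranking.index[:n_top])
    dominant = sorted([p for p in phylum_counts.columns if ubiquitous[p] and p in top])
    if not dominant:
        logger.warning("no phylum is present in every sample; all mass goes to 'Other'")
    table = rel[dominant].copy()
    table["Other"] = 1.0 - table.sum(axis=1)
    return table, dominant


def richness(counts: pd.DataFrame) -> pd.Series:
    """Number of ASVs with count > 0 per sample (computed on rarefied data)."""
    return (counts > 0).sum(axis=1).rename("richness")


def bray_curtis(counts: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities, BC(x,y) = sum|x-y| / sum(x+y)."""
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise DataError("abundances must be non-negative")
    zero = mat.sum(axis=1) == 0
    if zero.any():
        bad = [str(s) for s, z in zip(counts.index, zero) if z]
        raise DataError(f"all-zero samples have undefined dissimilarity: {', '.join(bad)}")
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(mat, metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(s) for s in counts.index])


@dataclass
class OrdinationResult:
    """NMDS configuration with Kruskal stress-1 and provenance."""

    scores: pd.DataFrame
    stress: float
    converged: bool
    seed: int | None
    n_restarts: int


def _stress1(dissimilarities: np.ndarray, config: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against observed dissimilarities.

    Fitted distances are regressed monotonically (isotonic) on the observed
    dissimilarities; stress-1 = sqrt(sum (dhat - d)^2 / sum d^2).
    """
    iu = np.triu_indices(dissimilarities.shape[0], k=1)
    delta = dissimilarities[iu]
    diff = config[:, None, :] - config[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))[iu]
    order = np.argsort(delta, kind="mergesort")
    iso = IsotonicRegression()
    dhat = np.empty_like(d)
    dhat[order] = iso.fit_transform(np.arange(order.size), d[order])
    denom = float((d**2).sum())
    if denom == 0:
        return math.inf
    return math.sqrt(float(((dhat - d) ** 2).sum()) / denom)


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:k]
    comp = vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0, None))
    return comp


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    seed: int | None = 0,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> OrdinationResult:
    """Non-metric multidimensional scaling of a dissimilarity matrix.

    Minimizes Kruskal stress-1 via SMACOF with monotone (isotonic)
    regression, taking the best of ``n_restarts`` starts (a classical
    metric-MDS initialization plus random restarts). The returned axes are
    centred, rotated to principal axes, and sign-fixed so the first
    nonzero score on each axis is positive.
    """
    if k < 1:
        raise DataError("k must be >= 1")
    d = dm.data
    rng = np.random.default_rng(seed)
    inits = [_classical_mds(d, k)]
    scale = max(d.max(), 1e-12)
    for _ in range(max(0, n_restarts - 1)):
        inits.append(rng.normal(scale=scale, size=(d.shape[0], k)))
    best_cfg, best_stress = None, math.inf
    for init in inits:
        cfg, _ = smacof(
            d,
            metric=False,
            n_components=k,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=tol,
            normalized_stress=True,
            random_state=0,
        )
        s = _stress1(d, cfg)
        if s < best_stress:
            best_stress, best_cfg = s, cfg
    assert best_cfg is not None
    cfg = best_cfg - best_cfg.mean(axis=0)
    # principal-axis rotation, then sign convention
    _, _, vt = np.linalg.svd(cfg, full_matrices=False)
    cfg = cfg @ vt.T
    for j in range(cfg.shape[1]):
        nz = np.nonzero(cfg[:, j])[0]
        if nz.size and cfg[nz[0], j] < 0:
            cfg[:, j] *= -1
    scores = pd.DataFrame(
        cfg, index=list(dm.ids), columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    converged = best_stress < math.inf
    return OrdinationResult(scores, best_stress, converged, seed, len(inits))


def hellinger(counts: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Hellinger transform: sqrt(count / row sum); rows get unit L2 norm."""
    mat = np.asarray(counts, dtype=float)
    if (mat < 0).any():
        raise DataError("abundances must be non-negative")
    sums = mat.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        raise DataError("rows with zero total cannot be Hellinger-transformed")
    out = np.sqrt(mat / sums)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def multiplicative_replacement(rel: np.ndarray, pseudocount: float | None = None) -> np.ndarray:
    """Replace zeros in a composition with a small delta, rescaling nonzeros.

    ``pseudocount`` defaults to half the smallest nonzero relative
    abundance in the matrix.
    """
    rel = np.asarray(rel, dtype=float)
    if pseudocount is None:
        nz = rel[rel > 0]
        if nz.size == 0:
            raise DataError("matrix is entirely zero")
        pseudocount = 0.5 * nz.min()
    if pseudocount <= 0:
        raise DataError("pseudocount must be positive")
    out = rel.copy()
    for i in range(out.shape[0]):
        zeros = out[i] == 0
        kz = int(zeros.sum())
        if kz:
            out[i, zeros] = pseudocount
            out[i, ~zeros] *= 1.0 - kz * pseudocount
    return out


def clr(
    counts: pd.DataFrame | np.ndarray, pseudocount: float | None = None
) -> pd.DataFrame | np.ndarray:
    """Centred log-ratio transform with multiplicative zero replacement.

    Rows are closed to relative abundances first (CLR is scale-invariant),
    zeros replaced, then ln(x_i) - mean(ln x). Output rows sum to zero.
    """
    mat = np.asarray(counts, dtype=float)
    if (mat < 0).any():
        raise DataError("abundances must be non-negative")
    sums = mat.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        raise DataError("rows with zero total cannot be CLR-transformed")
    rel = mat / sums
    rel = multiplicative_replacement(rel, pseudocount)
    out = _skbio_clr(rel)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out
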
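"""Selective-genotyping validation: single-marker LOD scan and concordance.

Extreme individuals from a large F2 are genotyped at a sparse marker panel
(e.g. KASP assays across a candidate interval). Each marker is scored with
a single-marker likelihood-ratio LOD comparing genotype-class means
(additive + dominance, three free means) against the grand mean:

    LOD = (n / 2) * log10(RSS0 / RSS1)

Because individuals are phenotypic extremes, LOD magnitudes are inflated
relative to a random sample; they are used for ranking markers, not for
effect estimation. Genotype codes: 0 = PR homozygote, 1 = heterozygote,
2 = PS homozygote, NaN = missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from bsaqtl.errors import DataError

__all__ = ["single_marker_lod", "genotype_concordance"]


def single_marker_lod(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    markers: pd.DataFrame | None = None,
    min_per_class: int = 2,
) -> pd.DataFrame:
    """LOD profile over markers from genotype-class means.

    ``genotypes`` is individuals x markers (codes 0/1/2, NaN missing).
    Markers with fewer than two genotype classes holding at least
    ``min_per_class`` individuals each are reported missing. A constant
    phenotype gives LOD 0 everywhere.
    """
    G = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if G.ndim != 2 or G.shape[0] != y.size:
        raise DataError("genotype matrix and phenotype length mismatch")
    if np.all(np.isnan(y)):
        raise DataError("all phenotypes missing")
    rows = []
    for j in range(G.shape[1]):
        g = G[:, j]
        ok = ~np.isnan(g) & ~np.isnan(y)
        gj, yj = g[ok], y[ok]
        n = yj.size
        means = {c: np.nan for c in (0, 1, 2)}
        classes = []
        for c in (0, 1, 2):
            vals = yj[gj == c]
            if vals.size:
                means[c] = float(vals.mean())
            if vals.size >= min_per_class:
                classes.append(c)
        if len(classes) < 2 or n < 4:
            rows.append({"lod": np.nan, "n": n, **{f"mean_{c}": means[c] for c in (0, 1, 2)}})
            continue
        rss0 = float(np.sum((yj - yj.mean()) ** 2))
        rss1 = 0.0
        for c in (0, 1, 2):
            vals = yj[gj == c]
            if vals.size:
                rss1 += float(np.sum((vals - vals.mean()) ** 2))
        if rss0 == 0.0 or rss1 == 0.0:
            # constant phenotype -> no signal; perfect class fit -> unbounded
            lod = 0.0 if rss0 == 0.0 else np.inf
        else:
            lod = max(0.5 * n * np.log10(rss0 / rss1), 0.0)
        rows.append({"lod": lod, "n": n, **{f"mean_{c}": means[c] for c in (0, 1, 2)}})
    out = pd.DataFrame(rows)
    if markers is not None:
        out = pd.concat([markers.reset_index(drop=True), out], axis=1)
    return out


def genotype_concordance(
    genotypes: np.ndarray,
    classes: np.ndarray,
    marker: int,
) -> pd.DataFrame:
    """Phenotype-class x genotype contingency at one marker.

    ``classes`` labels each individual (e.g. 'tolerant'/'susceptible').
    Returns counts per genotype code plus row fractions over non-missing
    calls; a class with no calls has missing fractions.
    """
    g = np.asarray(genotypes, dtype=float)[:, marker]
    cls = np.asarray(classes)
    rows = []
    for label in pd.unique(cls):
        sel = g[cls == label]
        called = sel[~np.isnan(sel)]
        counts = {f"n_{c}": int(np.sum(called == c)) for c in (0, 1, 2)}
        total = called.size
        fracs = {
            f"frac_{c}": (counts[f"n_{c}"] / total if total else np.nan) for c in (0, 1, 2)
        }
        rows.append({"class": label, "n_called": total, **counts, **fracs})
    return pd.DataFrame(rows)
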
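"""Simple diagnostic plots: marker-incidence Manhattan and F_ROH scatter."""

from __future__ import annotations

import numpy as np

from .genotype_io import SNPMap
from .rohi import MarkerPValues


def manhattan(
    snpmap: SNPMap,
    pvals: MarkerPValues,
    ax=None,
    alpha_line: float = 0.01,
):
    """Manhattan-style plot of -log10(p) per marker with the significance line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    for i, chrom in enumerate(snpmap.chromosomes()):
        sl = snpmap.chrom_slice(chrom)
        x = offset + np.arange(sl.stop - sl.start)
        ax.scatter(
            x, pvals.neg_log10_p[sl], s=4,
            color="steelblue" if i % 2 == 0 else "darkorange", label=None,
        )
        offset = x[-1] + 1
    ax.axhline(-np.log10(alpha_line), ls=":", color="grey")
    ax.set_xlabel("marker (genome order)")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    return ax


def froh_phenotype_scatter(froh_values, phenotypes, ax=None):
    """Scatter of per-individual genome F_ROH against the fertility pseudophenotype."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(froh_values, phenotypes, s=8, alpha=0.6, color="seagreen")
    ax.set_xlabel(r"$F_{ROH}$")
    ax.set_ylabel("Re_dEBV")
    return ax
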
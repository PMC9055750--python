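"""Plotting helpers for fitted results and CNV profiles."""

from __future__ import annotations

import numpy as np

from .cnv import CNVProfile
from .model import PGTLinkageResults


def plot_haplotype_map(results: PGTLinkageResults, ax=None):
    """Marker-by-embryo map of linkage votes, one panel per parental side.

    Mirrors the clinic's haplotype table: green for the disease-linked
    (H0) allele, grey for the normal (H1) allele, yellow for dropout
    abstentions.
    """
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    from .calling import _vote_at_site

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    sites = [s for s in results.haplotypes.sites if s.status == "resolved"]
    sites = sorted(sites, key=lambda s: (s.snp.side, s.snp.pos))
    embryos = [obs.embryo for obs in results.model.observations]
    grid = np.full((len(sites), len(embryos)), 2.0)
    for j, obs in enumerate(results.model.observations):
        med = obs.median_panel_depth()
        by_pos = {int(p): i for i, p in enumerate(obs.snps["pos"].to_numpy())}
        for i, ps in enumerate(sites):
            k = by_pos.get(ps.snp.pos)
            if k is None:
                continue
            row = obs.snps.iloc[k]
            alleles = tuple(a for a, d in ((row.ref, row.ref_depth),
                                           (row.alt, row.alt_depth)) if d > 0)
            vote = _vote_at_site(ps, alleles, float(row.ref_depth + row.alt_depth),
                                 med, 0.7)
            grid[i, j] = {"H0": 0.0, "H1": 1.0, None: 2.0}[vote]
    cmap = ListedColormap(["#2e8b57", "#c0c0c0", "#ffd700"])
    ax.imshow(grid, aspect="auto", cmap=cmap, vmin=0, vmax=2)
    ax.set_xticks(range(len(embryos)), embryos)
    ax.set_yticks(range(len(sites)),
                  [f"{s.snp.side[0].upper()}:{s.snp.pos}" for s in sites],
                  fontsize=6)
    ax.set_xlabel("embryo")
    ax.set_title(f"{results.model.family}: linkage votes "
                 "(green H0, grey H1, yellow ADO)")
    return ax


def plot_cnv_profile(profile: CNVProfile, ax=None):
    """Genome-wide normalized bin ratios with per-chromosome medians."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    bins = profile.bins.reset_index(drop=True)
    ax.scatter(bins.index, bins["ratio"], s=2, color="#444444")
    offset = 0
    for chrom, grp in bins.groupby("chrom", sort=False):
        mid = offset + len(grp) / 2
        call = next(c for c in profile.chromosomes if c.chrom == chrom)
        color = "#2e8b57" if call.call == "euploid" else "#b22222"
        ax.hlines(call.ratio, offset, offset + len(grp), color=color, lw=2)
        ax.text(mid, 1.75, chrom.removeprefix("chr"), ha="center", fontsize=6)
        offset += len(grp)
    ax.axhline(1.0, color="#888888", ls="--", lw=0.5)
    ax.set_ylim(0, 2)
    ax.set_ylabel("normalized ratio")
    ax.set_title(f"{profile.embryo}: {profile.call}")
    return ax
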
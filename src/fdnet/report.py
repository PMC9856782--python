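"""Plain-text report rendering for completed analyses."""

from __future__ import annotations

from io import StringIO

from .model import CovarianceNetworkResults, GroupComparisonResults

__all__ = ["render_report"]


def _module_section(res: CovarianceNetworkResults, buf: StringIO) -> None:
    listing = res.module_listing()
    print(
        f"\nModules — group '{res.group_label}' "
        f"({res.partition.n_modules} modules, Q = {res.partition.q:.4f})",
        file=buf,
    )
    for mid in range(1, res.partition.n_modules + 1):
        sub = listing[listing["module_id"] == mid]
        print(f"  Module {mid} ({len(sub)} nodes)", file=buf)
        for hemi in ("L", "R"):
            names = sub[sub["hemisphere"] == hemi]["abbreviation"].tolist()
            if names:
                print(f"    {hemi}: {', '.join(names)}", file=buf)


def render_report(results: GroupComparisonResults) -> str:
    """One human-readable document: regional table, module listings,
    per-lobe link counts and intra-/inter-lobular connectivity with ratios.

    The permutation section is included only when that stage was run.
    """
    buf = StringIO()
    la, lb = results.results_a.group_label, results.results_b.group_label
    print("FD-based structural covariance network comparison", file=buf)
    print("=" * 52, file=buf)

    print(f"\nRegional FD comparison ({la} vs {lb})", file=buf)
    cols = [
        "abbreviation",
        "lobe",
        f"mean_{la}",
        f"sd_{la}",
        f"mean_{lb}",
        f"sd_{lb}",
        "p",
        "q",
        "effect_size",
    ]
    sig = results.regional.significant()
    print(
        f"{len(sig)} of {len(results.regional.table)} regions significant "
        f"(q < {results.regional.alpha})",
        file=buf,
    )
    if len(sig):
        print(sig[cols].round(4).to_string(index=False), file=buf)

    _module_section(results.results_a, buf)
    _module_section(results.results_b, buf)

    for res in (results.results_a, results.results_b):
        print(f"\nWithin-lobe link counts — group '{res.group_label}' (L/R/B)", file=buf)
        print(
            res.lobes.table[["links_L", "links_R", "links_B"]].to_string(), file=buf
        )

    print(f"\nIntra-lobular connectivity (mode '{results.results_a.lobes.mode}')", file=buf)
    intra = results.ratios[["intra_ratio_pct"]].copy()
    intra.insert(0, la, results.results_a.lobes.table["intra"])
    intra.insert(1, lb, results.results_b.lobes.table["intra"])
    print(intra.round(4).to_string(), file=buf)

    print("\nInter-lobular connectivity (mean participation)", file=buf)
    inter = results.ratios[["inter_ratio_pct"]].copy()
    inter.insert(0, la, results.results_a.lobes.table["inter"])
    inter.insert(1, lb, results.results_b.lobes.table["inter"])
    print(inter.round(4).to_string(), file=buf)

    if results.permutation is not None:
        print(
            f"\nPermutation test ({results.permutation.n_perm} iterations, "
            f"subsample {results.permutation.subsample} per group)",
            file=buf,
        )
        print(results.permutation.to_frame().round(4).to_string(), file=buf)
    return buf.getvalue()
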
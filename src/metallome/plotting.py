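"""Optional figure emission: quota-vs-metallome scatter and volcano plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .compare import CorrelationResult, DifferentialResult


def plot_correlation(result: CorrelationResult, path: str | Path) -> None:
    """Log-log scatter of measured quota vs inferred metal abundance."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    x = result.pairs["quota"].to_numpy()
    y = result.pairs["abundance"].to_numpy()
    ax.loglog(x, y, "o", color="tab:blue")
    for _, row in result.pairs.iterrows():
        ax.annotate(row["metal"], (row["quota"], row["abundance"]),
                    textcoords="offset points", xytext=(4, 4), fontsize=8)
    ax.set_xlabel("metal quota (mmol/mol C)")
    ax.set_ylabel("inferred metallome (arbitrary units)")
    ax.set_title(f"$r^2$ = {result.r_squared:.2f} (n = {result.n_points})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_volcano(results: list[DifferentialResult], path: str | Path,
                 alpha: float = 0.05) -> None:
    """Volcano plot; filled markers are significant, open are not."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    fc = np.array([r.log2_fold_change for r in results])
    p = np.array([r.p_value for r in results])
    ok = ~(np.isnan(fc) | np.isnan(p))
    sig = np.array([r.significant for r in results]) & ok
    logp = -np.log10(np.clip(p, 1e-300, None))
    ax.scatter(fc[ok & ~sig], logp[ok & ~sig], facecolors="none",
               edgecolors="gray", s=18, label="n.s.")
    ax.scatter(fc[sig], logp[sig], color="tab:red", s=18, label=f"p < {alpha:g}")
    ax.axhline(-np.log10(alpha), ls="--", lw=0.8, color="black")
    ax.set_xlabel("log$_2$ fold change")
    ax.set_ylabel("$-\\log_{10} p$")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
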
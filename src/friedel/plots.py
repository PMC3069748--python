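"""Small diagnostic plots: anomalous signal by resolution shell and the
figure-of-merit trajectory across density-modification cycles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_bijvoet_ratio_by_shell(table, path=None, label="data"):
    """Bijvoet ratio |dF|/|F| per resolution shell (overall row dropped).

    ``table`` is the DataFrame from :func:`friedel.fa.anomalous_signal_by_shell`.
    """
    shells = table[table["shell"] >= 0]
    x = 1.0 / shells["d_min"] ** 2
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(x, shells["bijvoet_ratio"], "o-", label=label)
    ax.set_xlabel(r"$1/d^2$ ($\mathrm{\AA}^{-2}$)")
    ax.set_ylabel(r"$\langle|\Delta F|\rangle / \langle|F|\rangle$")
    ax.set_title("Bijvoet ratio by resolution shell")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def plot_dm_cycles(log, path=None):
    """Mean figure of merit (and, when available, true mean cosine phase
    error) per density-modification cycle.

    ``log`` is the per-cycle list from :class:`friedel.density.DMResults`.
    """
    cycles = [rec["cycle"] for rec in log]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(cycles, [rec["mean_fom"] for rec in log], "o-", label="mean FOM")
    if log and "mean_cos_err" in log[0]:
        ax.plot(cycles, [rec["mean_cos_err"] for rec in log], "s--",
                label=r"$\langle\cos\Delta\varphi\rangle$ (truth)")
    ax.set_xlabel("density-modification cycle")
    ax.set_ylabel("value")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
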
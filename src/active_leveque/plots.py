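"""Optional plotting helpers (requires the ``plot`` extra).

These read the tabular outputs of the pipeline; nothing downstream depends
on figures.
"""

from __future__ import annotations

import numpy as np


def _mpl():
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover - extra not installed
        raise ImportError(
            "plotting requires matplotlib; install the 'plot' extra"
        ) from exc
    return plt


def plot_sweep(df, ax=None):
    """Dimensional net adhesion rate vs shear rate, simulation and theory."""
    plt = _mpl()
    ax = ax or plt.gca()
    ax.errorbar(
        df["shear_rate"], df["sim_rate_dim"], yerr=df["sim_rate_dim_sd"],
        fmt="o", capsize=3, label="agent-based",
    )
    ax.plot(df["shear_rate"], df["theory_rate_dim"], "-", label="active Lévêque")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"shear rate $\dot\gamma$ (1/s)")
    ax.set_ylabel(r"net adhesion rate $J_A\dot\gamma$ (per unit inlet density)")
    ax.legend()
    return ax


def plot_collapse(df, ax=None):
    """Scaled net adhesion J̄ vs rotational Péclet number."""
    plt = _mpl()
    ax = ax or plt.gca()
    ax.errorbar(df["rot_peclet"], df["jbar_sim"], yerr=df["jbar_sim_sd"],
                fmt="o", capsize=3, label="agent-based")
    per = np.geomspace(df["rot_peclet"].min(), df["rot_peclet"].max(), 200)
    from .theory import collapsed_net_adhesion

    ax.plot(per, [collapsed_net_adhesion(3.0, p) for p in per], "-",
            label="theory collapse")
    ax.set_xscale("log")
    ax.set_xlabel(r"$Pe_r$")
    ax.set_ylabel(r"$\bar J$")
    ax.legend()
    return ax


def plot_density(field, comparison=None, ax=None):
    """Normalised density map with the 50% contours overlaid."""
    plt = _mpl()
    ax = ax or plt.gca()
    mesh = ax.pcolormesh(
        field.x_edges, field.y_edges, field.normalized.T, vmin=0, vmax=1.2,
        shading="auto",
    )
    plt.colorbar(mesh, ax=ax, label="normalised density")
    if comparison is not None:
        ax.plot(comparison.contour_x, comparison.contour_sim, "w.", label="sim 50%")
        ax.plot(comparison.contour_x, comparison.contour_theory, "r-",
                label="theory 50%")
        ax.legend(loc="upper right")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    return ax


def plot_regime_map(df, markers=None, ax=None):
    """Peeff colormap over (Per, Vs) with regime labels and scenario markers."""
    plt = _mpl()
    ax = ax or plt.gca()
    per = np.sort(df["Per"].unique())
    vs = np.sort(df["Vs"].unique())
    z = np.log10(df.pivot(index="Vs", columns="Per", values="Peeff").values)
    mesh = ax.pcolormesh(per, vs, z, shading="auto")
    plt.colorbar(mesh, ax=ax, label=r"$\log_{10} Pe_{\rm eff}$")
    if markers is not None:
        for sp, sub in markers.groupby("species"):
            ax.scatter(sub["Per"], sub["Vs"], label=sp, edgecolor="k")
        ax.legend()
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"$Pe_r$")
    ax.set_ylabel(r"$\mathcal{V}_s$")
    return ax
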
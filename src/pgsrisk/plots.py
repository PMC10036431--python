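"""Static figure exports: PS-decile incidence, calibration, decision curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_decile_incidence(deciles, path, title="Incidence by PS decile"):
    """Bar plot of observed (and predicted, if present) incidence by decile."""
    fig, ax = plt.subplots(figsize=(6, 4))
    x = deciles["group"]
    ax.bar(x, deciles["observed_incidence"], width=0.6, label="observed",
           color="#4878d0")
    if "predicted_incidence" in deciles.columns:
        ax.plot(x, deciles["predicted_incidence"], "o-", color="#d65f5f",
                label="predicted")
    ax.set_xlabel("PS decile")
    ax.set_ylabel("cumulative incidence")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_calibration(bins, path, title="Calibration"):
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.errorbar(bins["mean_predicted"], bins["observed_incidence"],
                yerr=[bins["observed_incidence"] - bins["observed_lo95"],
                      bins["observed_hi95"] - bins["observed_incidence"]],
                fmt="o", color="#4878d0")
    lim = max(bins["mean_predicted"].max(),
              bins["observed_incidence"].max()) * 1.05
    ax.plot([0, lim], [0, lim], "--", color="grey", lw=1)
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("observed incidence (KM)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_decision_curve(dc, path, title="Decision curve"):
    """Net benefit against threshold probability for each model."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, grp in dc.table.groupby("model"):
        style = {"treat_all": {"color": "grey", "ls": "--"},
                 "treat_none": {"color": "black", "ls": ":"}}.get(label, {})
        ax.plot(grp["pt"], grp["net_benefit"], label=label, **style)
    ax.set_xlabel("threshold probability $p_t$")
    ax.set_ylabel("net benefit")
    ax.set_ylim(bottom=min(-0.01, dc.table["net_benefit"].min()))
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
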
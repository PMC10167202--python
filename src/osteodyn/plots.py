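"""Four-panel trajectory figure: cells, bone mass, and phase portrait."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .simulate import Trajectory  # noqa: E402


def four_panel(traj: Trajectory, title: str = ""):
    """x1(t), x2(t), z(t) and the x1-x2 phase portrait on one figure."""
    fig, axes = plt.subplots(2, 2, figsize=(10, 7))
    (ax1, ax2), (ax3, ax4) = axes
    ax1.plot(traj.t, traj.x1, lw=0.9)
    ax1.set_xlabel("time (days)")
    ax1.set_ylabel("osteoclasts $x_1$")
    ax2.plot(traj.t, traj.x2, lw=0.9, color="tab:orange")
    ax2.set_xlabel("time (days)")
    ax2.set_ylabel("osteoblasts $x_2$")
    ax3.plot(traj.t, traj.z, lw=0.9, color="tab:green")
    ax3.set_xlabel("time (days)")
    ax3.set_ylabel("bone mass (%)")
    ax4.plot(traj.x1, traj.x2, lw=0.7, color="tab:red")
    ax4.set_xlabel("$x_1$")
    ax4.set_ylabel("$x_2$")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig
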
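"""Summary figures: posture scatter and speed profiles."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

_STATE_COLORS = {"stable": "tab:blue", "unstable": "tab:orange"}


def posture_scatter(samples: pd.DataFrame, path: str | Path) -> None:
    """Progression-vs-height scatter colored by trial state.

    Expects columns ``progression``, ``height``, ``state``.
    """
    fig, ax = plt.subplots(figsize=(5, 4))
    for state, g in samples.groupby("state"):
        ax.scatter(g["progression"], g["height"], s=8, alpha=0.5,
                   color=_STATE_COLORS.get(state, "gray"), label=state)
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("nose progression (cm)")
    ax.set_ylabel("nose height (cm)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def speed_profile_plot(profiles_by_state: dict[str, list],
                       path: str | Path) -> None:
    """Mean baselined speed per segment for each trial state."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for state, profiles in profiles_by_state.items():
        arr = np.vstack([p.baselined for p in profiles])
        mean = np.nanmean(arr, axis=0)
        ax.plot(mean, marker="o",
                color=_STATE_COLORS.get(state, "gray"), label=state)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("course segment")
    ax.set_ylabel("baselined speed (cm/s)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
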
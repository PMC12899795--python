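"""Optional plotting helpers (requires matplotlib).

The radar (spider) plot follows the display convention: sample entropy
and the Lyapunov exponent are inverted and ML step symmetry is shown as
an absolute value, so a larger radius always means "better" (more
symmetric, more stable, more regular, smoother).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DISPLAY_NEGATE = ("lyapunov", "saen")


def _display_frame(profiles: pd.DataFrame, outcomes: list[str]) -> pd.DataFrame:
    disp = profiles[outcomes].copy()
    for col in disp.columns:
        metric = col.rsplit("_", 1)[0]
        if metric in DISPLAY_NEGATE:
            disp[col] = -disp[col]
        if col == "step_symmetry_ml":
            disp[col] = disp[col].abs()
    return disp


def radar_plot(profiles: pd.DataFrame, out_path, group_col: str = "group"):
    """Group-mean spider plot of all outcome columns in a profiles table.

    Each outcome is min-max scaled across trials so axes are comparable;
    radius toward the edge = better gait quality under the display
    convention.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    meta = {"participant_id", group_col, "gender", "condition", "walking_speed"}
    outcomes = [c for c in profiles.columns if c not in meta]
    disp = _display_frame(profiles, outcomes)
    rng = disp.max() - disp.min()
    rng[rng == 0] = 1.0
    scaled = (disp - disp.min()) / rng
    scaled[group_col] = profiles[group_col].to_numpy()

    means = scaled.groupby(group_col).mean()
    angles = np.linspace(0, 2 * np.pi, len(outcomes), endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(7, 7))
    for name, row in means.iterrows():
        vals = row[outcomes].to_numpy(dtype=float)
        ax.plot(np.r_[angles, angles[0]], np.r_[vals, vals[0]], label=str(name))
        ax.fill(np.r_[angles, angles[0]], np.r_[vals, vals[0]], alpha=0.15)
    ax.set_xticks(angles)
    ax.set_xticklabels(outcomes, fontsize=7)
    ax.set_yticklabels([])
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1))
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
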
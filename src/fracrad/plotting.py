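"""Minimal trajectory and prediction plots (matplotlib)."""

from __future__ import annotations

__all__ = ["plot_trajectory", "plot_prediction"]


def plot_trajectory(traj, ax=None, label=None):
    """Plot proliferative, senescent and total confluence over time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(traj.times, traj.N_total, label=label or "total")
    ax.plot(traj.times, traj.N_p, "--", alpha=0.7, label="proliferative")
    if traj.N_s.any():
        ax.plot(traj.times, traj.N_s, ":", alpha=0.7, label="senescent")
    ax.set_xlabel("time (hr)")
    ax.set_ylabel("confluence")
    ax.legend()
    return ax


def plot_prediction(pred, curve=None, ax=None):
    """Predicted mean with its pointwise interval, optionally over the data."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(pred.times, pred.mean, color="C3", label="prediction")
    ax.fill_between(pred.times, pred.lower, pred.upper, color="C3", alpha=0.25,
                    label=f"{pred.level:.0%} {pred.interval} interval")
    if curve is not None:
        ax.plot(curve.times, curve.confluence, "o", ms=3, color="C0",
                label=f"replicate {curve.replicate_id}")
    ax.set_xlabel("time (hr)")
    ax.set_ylabel("confluence")
    ax.legend()
    return ax
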
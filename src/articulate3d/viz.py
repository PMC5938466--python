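"""3D visualization of rotated joined structures.

One specimen per figure: structure-1 landmarks in black, structure-2
landmarks in red (the conventional colors for a joined two-structure
plot), distinguished through the joined dataset's provenance tags.
"""

from __future__ import annotations

from .datasets import JoinedDataset

__all__ = ["plot_rotation_3d"]


def plot_rotation_3d(
    joined: JoinedDataset,
    specimen: int | str | None = None,
    colors: tuple[str, str] = ("black", "red"),
    out_path=None,
    show: bool = False,
):
    """Scatter one specimen of a joined dataset in 3D.

    Parameters
    ----------
    joined : JoinedDataset
        Must carry provenance tags (any product of ``join_arrays``).
    specimen : int (1-based), str id, or None
        Which specimen to draw; defaults to the first.
    colors : (str, str)
        Colors for structure 1 and structure 2.
    out_path : path-like, optional
        When given, the figure is written there (format from suffix).
    show : bool
        Open an interactive window (off by default; headless-safe).

    Returns the matplotlib figure.
    """
    if not isinstance(joined, JoinedDataset):
        raise TypeError("plot_rotation_3d needs a JoinedDataset with provenance tags")
    import matplotlib

    if out_path is not None and not show:
        matplotlib.use("Agg", force=True)
    import matplotlib.pyplot as plt

    if specimen is None:
        idx = 0
    elif isinstance(specimen, str):
        idx = joined.specimen_index(specimen)
    else:
        if not 1 <= specimen <= joined.specimen_count:
            raise IndexError(
                f"specimen {specimen} out of range 1..{joined.specimen_count}"
            )
        idx = specimen - 1

    pts = joined.coords[:, :, idx]
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="3d")
    for tag, color, label in ((1, colors[0], "structure 1"),
                              (2, colors[1], "structure 2")):
        mask = joined.provenance == tag
        ax.scatter(pts[mask, 0], pts[mask, 1], pts[mask, 2],
                   c=color, label=label, depthshade=False)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_zlabel("z")
    ax.set_title(f"specimen {joined.specimen_ids[idx]}")
    ax.legend()
    ax.set_box_aspect((1, 1, 1))
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    if show:  # pragma: no cover - interactive
        plt.show()
    else:
        plt.close(fig)
    return fig
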
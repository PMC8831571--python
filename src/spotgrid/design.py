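"""Physical layout of a spatial transcriptomics array.

The arrays targeted here are printed glass slides: a rectangular lattice of
spatially barcoded capture spots (100 µm diameter, 200 µm center-to-center
pitch, 33 columns × 35 rows by default, 1,007 of the lattice positions
carrying barcodes).  Every downstream module — rendering, detection, grid
fitting, registration — takes its geometry from an :class:`ArrayDesign`.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ArrayDesign:
    """Geometry of the printed spot lattice.

    Parameters
    ----------
    n_cols, n_rows
        Occupied lattice extent (columns × rows).
    spot_diameter_um
        Printed spot diameter in micrometers.
    pitch_um
        Center-to-center spot distance in micrometers.
    n_barcoded_positions
        Number of lattice nodes that carry a spatial barcode.  The full
        lattice (``n_cols * n_rows``) can exceed this; which nodes are
        unprinted is array-batch metadata, so the value is carried along
        but does not alter rendering or fitting.
    initial_grid_guess
        Grid points per row/column assumed by the first, rough grid fit
        before iterative refinement shrinks the layout to the target.
    """

    n_cols: int = 33
    n_rows: int = 35
    spot_diameter_um: float = 100.0
    pitch_um: float = 200.0
    n_barcoded_positions: int = 1007
    initial_grid_guess: int = 42

    def __post_init__(self) -> None:
        if self.n_cols < 2 or self.n_rows < 2:
            raise ValueError("grid needs at least 2 columns and 2 rows")
        if not self.spot_diameter_um < self.pitch_um:
            raise ValueError("spot diameter must be smaller than the pitch")
        if self.n_barcoded_positions > self.n_cols * self.n_rows:
            raise ValueError(
                "n_barcoded_positions cannot exceed the lattice size "
                f"({self.n_cols}x{self.n_rows}={self.n_cols * self.n_rows})"
            )

    @property
    def n_nodes(self) -> int:
        return self.n_cols * self.n_rows

    def pitch_px(self, um_per_px: float) -> float:
        """Lattice pitch in pixels at the given image scale."""
        if um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        return self.pitch_um / um_per_px

    def spot_radius_px(self, um_per_px: float) -> float:
        if um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        return 0.5 * self.spot_diameter_um / um_per_px


DEFAULT_DESIGN = ArrayDesign()
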
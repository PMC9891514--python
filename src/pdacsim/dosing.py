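"""Treatment protocols: how, where and when drug enters the TME.

A protocol is either free-drug point injection (one site, or four sites at
quarter turns each carrying a quarter of the dose) at a distance d_m (mm)
from the tumour centre, or implantation of a drug-loaded fibre whose line
source sits d_m from the centre.  Administration fires once, when the
measured tumour volume first reaches ``start_volume``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .fibre import FibreState, ReleaseLaw, fibre_init
from .lattice import Tissue
from .tme_field import DrugGrid, deposit_point


@dataclasses.dataclass
class Protocol:
    """A dosing specification.

    kind 'none' is the untreated control; 'injection' deposits
    total_dose/n_sites ug at each site instantaneously; 'fibre' implants a
    fibre loaded with total_dose ug releasing per ``release``.
    """

    kind: str = "none"
    n_sites: int = 1
    d_m: float = 0.0  # placement distance from tumour centre, mm
    total_dose: float = 500.0
    release: ReleaseLaw | None = None
    start_volume: float = 100.0  # mm^3 trigger
    fibre_r_total: float = 0.05  # mm
    fibre_length_mm: float = 5.0
    fibre_annuli: int = 24

    def __post_init__(self):
        if self.kind not in ("none", "injection", "fibre"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.n_sites not in (1, 4):
            raise ValueError("n_sites must be 1 or 4")
        if self.d_m < 0 or self.total_dose < 0:
            raise ValueError("d_m and total_dose must be nonnegative")
        if self.kind == "fibre" and self.release is None:
            self.release = ReleaseLaw(kind="fvm", c0=self.total_dose)
        self._administered = False


def place_sites(protocol: Protocol, tumour_centre, sigma: float,
                bounds=None) -> list[tuple[np.ndarray, float]]:
    """Site positions (model units) and per-site doses.

    n_sites points at radius d_m / sigma from the tumour centre; four sites
    sit at angles 0, pi/2, pi, 3pi/2 so the pattern is symmetric under a
    quarter turn.  Doses sum to total_dose.
    """
    centre = np.asarray(tumour_centre, dtype=float)
    radius = protocol.d_m / sigma
    if protocol.n_sites == 1:
        angles = [0.0]
    else:
        angles = [0.0, np.pi / 2, np.pi, 3 * np.pi / 2]
    dose = protocol.total_dose / protocol.n_sites
    sites = []
    for a in angles:
        p = centre + radius * np.array([np.cos(a), np.sin(a)])
        if bounds is not None:
            xmin, xmax, ymin, ymax = bounds
            if not (xmin <= p[0] <= xmax and ymin <= p[1] <= ymax):
                raise ValueError(
                    f"site {tuple(p)} falls outside domain bounds {bounds}; "
                    "enlarge the drug grid")
        sites.append((p, dose))
    return sites


def administer(protocol: Protocol, tissue: Tissue, grid: DrugGrid,
               fibre_slot: FibreState | None = None,
               tumour_centre=None) -> tuple[DrugGrid, FibreState | None]:
    """Fire the protocol once: deposit injections or construct the implant.

    The fibre line source is centred vertically on the tumour centre at a
    horizontal offset d_m / sigma; its J cross-sections align with the grid
    rows it spans.
    """
    if getattr(protocol, "_administered", False) or fibre_slot is not None:
        raise RuntimeError("protocol already administered")
    if tumour_centre is None:
        tm = tissue.tumour_mask
        tumour_centre = tissue.positions[tm].mean(axis=0) if tm.any() else \
            np.array([(tissue.bounds[0] + tissue.bounds[1]) / 2,
                      (tissue.bounds[2] + tissue.bounds[3]) / 2])
    if protocol.kind == "none":
        protocol._administered = True
        return grid, None
    if protocol.kind == "injection":
        for p, dose in place_sites(protocol, tumour_centre, tissue.sigma,
                                   bounds=grid.bounds):
            deposit_point(grid, p, dose)
        protocol._administered = True
        return grid, None
    # fibre: vertical line source at x = centre_x + d_m/sigma
    x_F = float(tumour_centre[0]) + protocol.d_m / tissue.sigma
    length_model = protocol.fibre_length_mm / tissue.sigma
    y0 = float(tumour_centre[1]) - length_model / 2.0
    xmin, xmax, ymin, ymax = grid.bounds
    if not (xmin <= x_F <= xmax and ymin <= y0 and y0 + length_model <= ymax):
        raise ValueError("fibre line source outside grid bounds; enlarge domain")
    yc = grid.y_centres
    J = int(((yc >= y0) & (yc <= y0 + length_model)).sum())
    law = dataclasses.replace(protocol.release, c0=protocol.total_dose)
    fib = fibre_init(law, protocol.fibre_r_total, protocol.fibre_length_mm,
                     M=protocol.fibre_annuli, x_F=x_F, y0=y0, J=max(J, 1))
    protocol._administered = True
    return grid, fib
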
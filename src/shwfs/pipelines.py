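"""The two end-to-end reconstruction pipelines.

* classical: per-sub-aperture window CoG centroids, identity assignment
  (each window's centroid belongs to its own lenslet by construction),
  modal solve.
* proposed: whole-frame matched-filter centroid extraction, point-set
  network assignment, modal solve.

Both share the same reconstruction operator, so within the classical
dynamic range they coincide; the proposed pipeline keeps working once
spots leave their sub-aperture windows.
"""

from __future__ import annotations

from .centroid import CorrelatorTemplate, cog_all, extract_centroids
from .forward_model import LensletGeometry, SpotFrame
from .matcher import MatchNetwork, assign
from .reconstruct import ReconOperator, ReconResult, reconstruct
from .zernike import ZernikeCoefficients

__all__ = ["classical_reconstruct", "proposed_reconstruct"]


def classical_reconstruct(
    frame: SpotFrame,
    op: ReconOperator,
    geometry: LensletGeometry | None = None,
    reference: ZernikeCoefficients | None = None,
    grid: int = 256,
) -> ReconResult:
    """Traditional pipeline: window CoG + identity assignment + modal solve."""
    geometry = geometry or frame.geometry
    centroids = cog_all(frame, geometry)
    return reconstruct(centroids, None, geometry, op, reference=reference, grid=grid)


def proposed_reconstruct(
    frame: SpotFrame,
    template: CorrelatorTemplate,
    net: MatchNetwork,
    op: ReconOperator,
    geometry: LensletGeometry | None = None,
    reference: ZernikeCoefficients | None = None,
    assignment_method: str = "greedy",
    grid: int = 256,
) -> ReconResult:
    """Whole-frame pipeline: matched-filter extraction + network matching +
    modal solve."""
    geometry = geometry or frame.geometry
    centroids = extract_centroids(frame, template, k=geometry.k_effective)
    assignment = assign(net, centroids, geometry, method=assignment_method)
    return reconstruct(
        centroids, assignment, geometry, op, reference=reference, grid=grid
    )
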
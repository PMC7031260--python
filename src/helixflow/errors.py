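"""Exception hierarchy.

All helixflow errors derive from :class:`HelixflowError` so callers can
catch the package's failures with a single except clause while still
distinguishing structural problems (grids that do not match) from domain
problems (a BSA from a non-positive weight).
"""


class HelixflowError(Exception):
    """Base class for all helixflow errors."""


class StructuralError(HelixflowError):
    """Incompatible array shapes / grids between inputs."""


class MetadataError(HelixflowError):
    """Required acquisition metadata missing or invalid."""


class DomainError(HelixflowError):
    """Input value outside the mathematical domain of an operation."""


class TopologyError(HelixflowError):
    """Mask topology prevents the requested geometric construction."""


class EmptyRegionError(HelixflowError):
    """A region (ROI, measuring plane) contains no voxels/samples."""


class UnderdeterminedError(HelixflowError):
    """Fewer observations than free parameters in a fit."""


class StageError(HelixflowError):
    """Pipeline stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
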
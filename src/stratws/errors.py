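"""Exception hierarchy.

All stratws errors derive from :class:`StratWSError` so callers can catch
library failures with a single except clause; each subclass also derives
from the closest builtin so generic handling (``except ValueError``) works.
"""


class StratWSError(Exception):
    """Base class for all stratws errors."""


class FormatError(StratWSError, ValueError):
    """Malformed input file (inconsistent columns, non-numeric rows, ...)."""


class SizeError(StratWSError, ValueError):
    """Input has the wrong number of points/rows for the operation."""


class ParameterError(StratWSError, ValueError):
    """Out-of-range or inconsistent parameter value."""


class EmptyInputError(StratWSError, ValueError):
    """Mask or volume contains no foreground."""


class DegenerateShapeError(StratWSError, ValueError):
    """All pairwise distances are zero; the shape carries no geometry."""


class ConnectivityError(StratWSError, ValueError):
    """kNN graph is disconnected; geodesic distances are undefined.

    Carries ``n_components`` so the caller knows how badly the graph is
    fragmented (the usual fix is raising k).
    """

    def __init__(self, n_components: int, k: int):
        self.n_components = n_components
        self.k = k
        super().__init__(
            f"kNN graph with k={k} has {n_components} connected components; "
            f"increase k to obtain finite geodesic distances"
        )


class GridMismatchError(StratWSError, ValueError):
    """Two stratified embeddings use incompatible (B, Q, q_grid) grids."""


class IndexSetError(StratWSError, ValueError):
    """Overlapping, empty, or out-of-range index sets for a kernel statistic."""


class LabelError(StratWSError, ValueError):
    """Group labels do not define the groups a test requires."""
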
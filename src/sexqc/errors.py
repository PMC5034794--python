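"""Exception hierarchy for sexqc."""


class SexQCError(Exception):
    """Base class for all sexqc errors."""


class FormatError(SexQCError):
    """Malformed expression-matrix or report file."""


class MetadataError(SexQCError):
    """Malformed or inconsistent sample metadata."""


class PreprocessError(SexQCError):
    """Preprocessing preconditions violated (scale, sample count)."""


class PanelError(SexQCError):
    """Invalid marker-panel configuration or panel/matrix mismatch."""


class ClusteringError(SexQCError):
    """Clustering preconditions violated."""


class DegenerateClusteringError(ClusteringError):
    """Best k-means solution has an empty cluster or coincident centroids.

    Usually signals a single-sex dataset or constant marker values.
    """


class LabelingError(SexQCError):
    """Cluster-to-sex labeling failed (tied centroid vote)."""


class ScoreError(SexQCError):
    """Median sex score undefined for a sample (missing marker direction)."""


class ReportError(SexQCError):
    """Inconsistent call/metadata pairing or corpus stratification."""


class SingleSexDatasetError(SexQCError):
    """Metadata annotates only one sex; inference is skipped."""
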
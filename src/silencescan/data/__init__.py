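"""Packaged synthetic PWM set.

These matrices are synthetic stand-ins written for this package: an
ETS-like matrix (GGAA core) used as the planted promoter motif, a
REL/NF-kB-like matrix, and a decoy with an unrelated consensus.
"""

from importlib import resources

__all__ = ["packaged_motifs", "packaged_motif_path"]


def packaged_motif_path():
    return resources.files(__package__) / "synthetic_motifs_jaspar.txt"


def packaged_motifs():
    from ..motifs import read_jaspar

    return read_jaspar(str(packaged_motif_path()))
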
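import numpy as np

from plisage.io_formats import ResidueBackbone


def rotate_backbone(bb: ResidueBackbone, R: np.ndarray, t: np.ndarray):
    """Apply a rigid motion to every backbone atom."""
    return ResidueBackbone(bb.aa_index, bb.n @ R.T + t, bb.ca @ R.T + t,
                           bb.c @ R.T + t, bb.o @ R.T + t, bb.cb @ R.T + t,
                           bb.resnames)
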
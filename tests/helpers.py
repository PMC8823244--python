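"""Shared helpers for building small test inputs."""

import pandas as pd

from usvdetect.audio_io import LabelTable


def make_table(rows, source="test"):
    """LabelTable from a list of (onset, offset, label) tuples."""
    return LabelTable(
        rows=pd.DataFrame(rows, columns=["onset", "offset", "label"]),
        source=source,
    )
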
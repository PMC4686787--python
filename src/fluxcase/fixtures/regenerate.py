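"""Regenerate the packaged ``.xpdl`` fixture files from the builders.

Run as ``python -m fluxcase.fixtures.regenerate``. Each file gets a leading
comment flagging which parts are reconstructions rather than published
protocol content.
"""

from __future__ import annotations

from pathlib import Path

from ..xpdl_io import serialize_workflow
from ._protocols import BUILDERS

_COMMENTS = {
    "nmo": (
        "Neuromyelitis optica protocol fixture. The 16-activity structure, the\n"
        "auto-identified Identification step, the Date of First Evaluation and\n"
        "the flexible Family History table are published facts; the remaining\n"
        "activity names and attribute lists are reconstructions for testing,\n"
        "not published medical content."
    ),
    "pcm": (
        "Paracoccidioidomycosis protocol fixture. The SAME identifier and the\n"
        "battery sizes (35 yes/no conditions, 29 yes/no present/previous\n"
        "diseases) are published facts; the numbered condition_NN/disease_NN\n"
        "labels are deliberate stand-ins - the individual item names are not\n"
        "published and are not invented here."
    ),
    "ald": (
        "Adrenoleukodystrophy protocol fixture. The 9-activity structure, the\n"
        "extensible treatment/symptom registries (defaults Fatigue, Leg Pain)\n"
        "and the suggestion feature are published facts; attribute details are\n"
        "reconstructions for testing."
    ),
}


def regenerate(target_dir: Path | None = None) -> list[Path]:
    target_dir = target_dir or Path(__file__).parent
    written = []
    for name, builder in BUILDERS.items():
        text = serialize_workflow(builder())
        declaration, rest = text.split("\n", 1)
        comment = "<!--\n" + _COMMENTS[name] + "\n-->\n"
        path = target_dir / f"{name}.xpdl"
        path.write_text(declaration + "\n" + comment + rest, encoding="utf-8")
        written.append(path)
    return written


if __name__ == "__main__":
    for path in regenerate():
        print(f"wrote {path}")
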
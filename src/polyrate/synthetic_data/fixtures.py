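"""Write simulated outputs to a fixture directory that round-trips through
the package's readers."""

from __future__ import annotations

from pathlib import Path

from .. import io

__all__ = ["write_fixtures"]


def write_fixtures(outputs: dict, directory: str | Path) -> dict[str, Path]:
    """Serialize simulator outputs.

    Recognized keys: ``history``, ``alignments``, ``presence``,
    ``ltr_pairs``, ``panel``, ``meth_tracks`` (dict context -> frame),
    ``contacts``, ``truth``.  Returns a map from key to written path (the
    alignments key maps to its directory).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    known = {
        "history", "alignments", "presence", "ltr_pairs",
        "panel", "meth_tracks", "contacts", "truth",
    }
    unknown = set(outputs) - known
    if unknown:
        raise KeyError(f"unrecognized fixture keys: {sorted(unknown)}")
    if "history" in outputs:
        written["history"] = io.write_history(outputs["history"], directory / "history.nwk")
    if "alignments" in outputs:
        io.write_alignments(outputs["alignments"], directory / "alignments")
        written["alignments"] = directory / "alignments"
    if "presence" in outputs:
        written["presence"] = io.write_presence(outputs["presence"], directory / "presence.tsv")
    if "ltr_pairs" in outputs:
        written["ltr_pairs"] = io.write_ltr_fasta(outputs["ltr_pairs"], directory / "ltr_pairs.fasta")
    if "panel" in outputs:
        written["panel"] = io.write_vcf(outputs["panel"], directory / "panel.vcf")
    if "meth_tracks" in outputs:
        for context, track in outputs["meth_tracks"].items():
            p = io.write_track(track, directory / f"meth_{context}.tsv")
            written[f"meth_{context}"] = p
    if "contacts" in outputs:
        written["contacts"] = io.write_table(outputs["contacts"], directory / "contacts.tsv")
    if "truth" in outputs:
        written["truth"] = io.write_truth(outputs["truth"], directory / "truth.json")
    return written
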
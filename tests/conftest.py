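import pytest

from opsinshift import simulate
from opsinshift.counts_io import metadata_frame
from opsinshift.expression import profile_table


@pytest.fixture(scope="session")
def paper_like_data():
    """One paper_like dataset: (counts, records, truth), fixed seed."""
    return simulate.generate_counts(simulate.preset("paper_like"), seed=42)


@pytest.fixture(scope="session")
def paper_like_profiles(paper_like_data):
    counts, records, _ = paper_like_data
    return profile_table(counts, metadata_frame(records))


@pytest.fixture()
def tsv_writer(tmp_path):
    """Write a TSV from header + rows and return its path."""

    def _write(name, header, rows):
        path = tmp_path / name
        lines = ["\t".join(header)]
        lines += ["\t".join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
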
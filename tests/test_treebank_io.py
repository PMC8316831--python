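import gzip

import pytest

from synnet.errors import ParseError, ValidationError
from synnet.treebank import (
    Sentence,
    Token,
    read_conllu,
    read_dependency_table,
    read_pajek,
    write_conllu,
    write_dependency_table,
    write_pajek,
)
from synnet.network import SyntacticNetwork, build_network

from tests.conftest import DEMO_TABLE_ROWS


class TestToken:
    def test_self_government_rejected(self):
        with pytest.raises(ValidationError, match="governs itself"):
            Token(order=2, form="x", governor_order=2, relation="DEP")

    def test_negative_governor_rejected(self):
        with pytest.raises(ValidationError):
            Token(order=1, form="x", governor_order=-1)


class TestSentence:
    def test_non_consecutive_orders_rejected(self):
        toks = (
            Token(order=1, form="a", governor_order=0, relation="HED"),
            Token(order=3, form="b", governor_order=1, relation="DEP"),
        )
        with pytest.raises(ValidationError, match="consecutive"):
            Sentence(sentence_id="s1", tokens=toks)

    def test_governor_out_of_range_rejected(self):
        toks = (
            Token(order=1, form="a", governor_order=0, relation="HED"),
            Token(order=2, form="b", governor_order=9, relation="DEP"),
        )
        with pytest.raises(ValidationError, match="s1"):
            Sentence(sentence_id="s1", tokens=toks)

    def test_two_roots_tolerated_with_warning(self):
        toks = (
            Token(order=1, form="a", governor_order=0, relation="HED"),
            Token(order=2, form="b", governor_order=0, relation="HED"),
        )
        with pytest.warns(UserWarning, match="2 root"):
            sent = Sentence(sentence_id="s1", tokens=toks)
        assert sent.root_count == 2


class TestReadDependencyTable:
    def test_demo_fixture_counts(self, demo_table_file):
        tb = read_dependency_table(demo_table_file)
        assert len(tb) == 2
        assert tb.token_count == 8
        assert [len(s) for s in tb] == [3, 5]

    def test_field_values(self, demo_table_file, toy_treebank):
        tb = read_dependency_table(demo_table_file)
        for parsed, expected in zip(tb.sentences, toy_treebank.sentences):
            assert parsed.sentence_id == expected.sentence_id
            assert parsed.tokens == expected.tokens

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("", encoding="utf-8")
        with pytest.raises(ParseError, match="no sentences"):
            read_dependency_table(path)

    def test_governor_out_of_range_names_sentence(self, tmp_path):
        rows = list(DEMO_TABLE_ROWS)
        rows[5] = "s2\t3\tXuexiao\tn\t9\tZai\tPOB"
        path = tmp_path / "bad.tsv"
        path.write_text("\n".join(rows) + "\n", encoding="utf-8")
        with pytest.raises(ValidationError, match="s2"):
            read_dependency_table(path)

    def test_wrong_column_count_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("s1\t1\tTa\tr\t2\n", encoding="utf-8")
        with pytest.raises(ParseError, match="line 1"):
            read_dependency_table(path)

    def test_root_relation_inconsistency_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("s1\t1\tTa\tr\t0\t/\tSBV\n", encoding="utf-8")
        with pytest.raises(ValidationError, match="inconsistent"):
            read_dependency_table(path)

    def test_governor_form_mismatch_warns(self, tmp_path):
        rows = list(DEMO_TABLE_ROWS)
        rows[0] = "s1\t1\tTa\tr\t2\tWRONG\tSBV"
        path = tmp_path / "mismatch.tsv"
        path.write_text("\n".join(rows) + "\n", encoding="utf-8")
        with pytest.warns(UserWarning, match="WRONG"):
            tb = read_dependency_table(path)
        # reported, not silently fixed: parsed token keeps its governor index
        assert tb.sentences[0].tokens[0].governor_order == 2

    def test_comments_and_blank_lines_ignored(self, tmp_path):
        text = "# comment\n\n" + "\n".join(DEMO_TABLE_ROWS) + "\n"
        path = tmp_path / "c.tsv"
        path.write_text(text, encoding="utf-8")
        assert read_dependency_table(path).token_count == 8

    def test_gzip_input(self, tmp_path):
        path = tmp_path / "demo.tsv.gz"
        with gzip.open(path, "wt", encoding="utf-8") as fh:
            fh.write("\n".join(DEMO_TABLE_ROWS) + "\n")
        assert read_dependency_table(path).token_count == 8


class TestRoundTrips:
    def test_table_round_trip_lossless(self, toy_treebank, tmp_path):
        path = tmp_path / "out.tsv"
        write_dependency_table(toy_treebank, path)
        again = read_dependency_table(path)
        assert again.sentences == toy_treebank.sentences

    def test_conllu_round_trip_identical(self, toy_treebank, tmp_path):
        path = tmp_path / "out.conllu"
        write_conllu(toy_treebank, path)
        again = read_conllu(path)
        assert again.sentences == toy_treebank.sentences


class TestReadConllu:
    def test_matches_table_dialect(self, demo_conllu_file, demo_table_file):
        a = read_conllu(demo_conllu_file)
        b = read_dependency_table(demo_table_file)
        assert a.sentences == b.sentences

    def test_blank_file_errors(self, tmp_path):
        path = tmp_path / "empty.conllu"
        path.write_text("\n\n", encoding="utf-8")
        with pytest.raises(ParseError, match="no sentences"):
            read_conllu(path)

    def test_non_integer_head_errors(self, tmp_path):
        path = tmp_path / "bad.conllu"
        path.write_text(
            "1\tTa\t_\tr\t_\t_\tX\tSBV\t_\t_\n", encoding="utf-8"
        )
        with pytest.raises(ParseError, match="HEAD"):
            read_conllu(path)

    def test_two_heads_accepted_with_warning(self, tmp_path):
        path = tmp_path / "frag.conllu"
        path.write_text(
            "1\ta\t_\tn\t_\t_\t0\tHED\t_\t_\n"
            "2\tb\t_\tn\t_\t_\t0\tHED\t_\t_\n",
            encoding="utf-8",
        )
        with pytest.warns(UserWarning, match="root"):
            tb = read_conllu(path)
        assert tb.sentences[0].root_count == 2

    def test_foreign_root_label_warns(self, tmp_path):
        path = tmp_path / "ud.conllu"
        path.write_text(
            "1\ta\t_\tNOUN\t_\t_\t0\troot\t_\t_\n", encoding="utf-8"
        )
        with pytest.warns(UserWarning, match="root"):
            read_conllu(path)

    def test_multiword_and_empty_nodes_skipped(self, tmp_path):
        path = tmp_path / "mw.conllu"
        path.write_text(
            "1-2\tab\t_\t_\t_\t_\t_\t_\t_\t_\n"
            "1\ta\t_\tn\t_\t_\t2\tDEP\t_\t_\n"
            "2\tb\t_\tv\t_\t_\t0\tHED\t_\t_\n"
            "2.1\tghost\t_\t_\t_\t_\t_\t_\t_\t_\n",
            encoding="utf-8",
        )
        tb = read_conllu(path)
        assert tb.token_count == 2

    def test_punct_flagged_from_upos(self, tmp_path):
        path = tmp_path / "p.conllu"
        path.write_text(
            "1\ta\t_\tNOUN\t_\t_\t0\tHED\t_\t_\n"
            "2\t.\t_\tPUNCT\t_\t_\t1\tpunct\t_\t_\n",
            encoding="utf-8",
        )
        tb = read_conllu(path)
        assert tb.sentences[0].tokens[1].is_punct


class TestPajek:
    def test_toy_network_export(self, toy_network, tmp_path):
        path = tmp_path / "toy.net"
        write_pajek(toy_network, path)
        lines = path.read_text(encoding="utf-8").splitlines()
        assert lines[0] == "*Vertices 5"
        edge_lines = lines[lines.index("*Edges") + 1 :]
        assert len(edge_lines) == 4

    def test_multiplicity_two_edge_weight(self, toy_network, tmp_path):
        path = tmp_path / "toy.net"
        write_pajek(toy_network, path)
        lines = path.read_text(encoding="utf-8").splitlines()
        edge_lines = lines[lines.index("*Edges") + 1 :]
        weights = sorted(int(line.split()[2]) for line in edge_lines)
        assert weights == [1, 1, 2, 2]

    def test_single_edge_network(self, tmp_path):
        net = SyntacticNetwork.from_edges([("a", "b")])
        path = tmp_path / "one.net"
        write_pajek(net, path)
        lines = path.read_text(encoding="utf-8").splitlines()
        assert lines[0] == "*Vertices 2"
        assert lines[-1].split() == ["1", "2", "1"]

    def test_empty_network_errors(self, tmp_path):
        with pytest.raises(ValidationError):
            write_pajek(SyntacticNetwork(), tmp_path / "x.net")

    def test_pajek_round_trip(self, toy_network, tmp_path):
        path = tmp_path / "toy.net"
        write_pajek(toy_network, path)
        again = read_pajek(path)
        assert again == toy_network
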
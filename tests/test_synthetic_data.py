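"""Synthetic substrate: determinism, integrity, recoverability, evaluation."""

import hashlib
import json
import sqlite3

import pytest

from carefuse.errors import AlignmentError, ConfigError
from carefuse.extraction import annotate_corpus, annotate_document
from carefuse.synthetic_data import (
    GroundTruth,
    SimConfig,
    evaluate_extraction,
    generate_databases,
    generate_keyword_corpus,
    generate_notes,
    generate_status_profile_corpus,
    write_run,
)
from carefuse.text_index import DocumentRecord


def sha(path):
    return hashlib.sha256(path.read_bytes()).hexdigest()


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        dict(n_patients=0),
        dict(noise_rate=1.5),
        dict(encounters_per_patient=(5, 5)),
        dict(smoking_distribution={"positive": 0.5, "negative": 0.2,
                                   "former": 0.2, "uncertain": 0.2}),
        dict(date_window=("2016-01-01", "2015-01-01")),
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimConfig(**kwargs).validate()


class TestDatabases:
    def test_patient_count_echoes_config(self, tmp_path):
        dips, mv, _ = generate_databases(SimConfig(seed=2, n_patients=10),
                                         tmp_path)
        for db in (dips, mv):
            n = sqlite3.connect(db).execute(
                "SELECT COUNT(*) FROM patient").fetchone()[0]
            assert n == 10

    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        cfg = SimConfig(seed=9, n_patients=5)
        d1, m1, _ = generate_databases(cfg, tmp_path / "a")
        d2, m2, _ = generate_databases(cfg, tmp_path / "b")
        assert sha(d1) == sha(d2)
        assert sha(m1) == sha(m2)

    def test_referential_integrity(self, tmp_path):
        dips, mv, _ = generate_databases(SimConfig(seed=4), tmp_path)
        for db, tables in ((dips, ("encounter", "measurement")),
                           (mv, ("measurement",))):
            conn = sqlite3.connect(db)
            for table in tables:
                orphans = conn.execute(
                    f"SELECT COUNT(*) FROM {table} t LEFT JOIN patient p "
                    "ON t.patient_id = p.id WHERE p.id IS NULL").fetchone()[0]
                assert orphans == 0

    def test_ssn_has_invalid_checksum_structure(self, tmp_path):
        dips, _, _ = generate_databases(SimConfig(seed=4), tmp_path)
        rows = sqlite3.connect(dips).execute(
            "SELECT ssn FROM patient").fetchall()
        for (ssn,) in rows:
            assert len(ssn) == 11 and ssn.isdigit()
            digits = [int(c) for c in ssn]
            w2 = [5, 4, 3, 2, 7, 6, 5, 4, 3, 2]
            k2 = (11 - sum(d * w for d, w in zip(digits[:10], w2)) % 11) % 11
            assert digits[10] != k2  # deliberately fails the second check


class TestNotes:
    def test_zero_mention_rates_give_empty_truth(self):
        cfg = SimConfig(seed=1, n_patients=2, notes_per_patient=(2, 5),
                        mention_rates={k: 0.0 for k in
                                       SimConfig().mention_rates},
                        smoking_rate=0.0, allergy_rate=0.0)
        docs, truth = generate_notes(cfg)
        assert docs
        assert all(not v for v in truth.vitals.values())
        assert all(not v for v in truth.statuses.values())

    def test_planted_values_appear_verbatim(self, pack_no):
        docs, truth = generate_notes(SimConfig(seed=8, n_patients=2,
                                               notes_per_patient=(5, 10)))
        for doc in docs:
            for measure, value in truth.vitals[doc.doc_id]:
                lex_int = str(int(value))
                lex_dec = f"{value:.1f}"
                assert (lex_int in doc.text or lex_dec in doc.text
                        or lex_dec.replace(".", ",") in doc.text)

    def test_noise_free_corpus_is_perfectly_recoverable(self, pack_no):
        docs, truth = generate_notes(SimConfig(seed=21, n_patients=3,
                                               notes_per_patient=(10, 25)))
        table = evaluate_extraction(annotate_corpus(docs, pack_no), truth)
        active = table[(table.tp + table.fn) > 0]
        assert (active.precision == 1.0).all()
        assert (active.recall == 1.0).all()

    def test_noise_degrades_recall_not_truth(self, pack_no):
        cfg = SimConfig(seed=21, n_patients=3, notes_per_patient=(10, 25),
                        noise_rate=0.5)
        docs, truth = generate_notes(cfg)
        table = evaluate_extraction(annotate_corpus(docs, pack_no), truth)
        assert table.fn.sum() > 0  # typos in keywords lose some items

    def test_determinism(self):
        cfg = SimConfig(seed=13, n_patients=2)
        assert generate_notes(cfg) == generate_notes(cfg)

    def test_status_frequencies_match_config_within_three_se(self):
        cfg = SimConfig(seed=17, n_patients=20, notes_per_patient=(50, 70),
                        smoking_rate=1.0)
        docs, truth = generate_notes(cfg)
        statuses = [s for v in truth.statuses.values()
                    for c, s in v if c == "smoking"]
        n = len(statuses)
        assert n >= 1000
        for status, p in cfg.smoking_distribution.items():
            observed = statuses.count(status) / n
            se = (p * (1 - p) / n) ** 0.5
            assert abs(observed - p) <= 3 * se


class TestKeywordCorpus:
    def test_exactly_n_matching_documents_of_requested_type(self):
        docs = generate_keyword_corpus(seed=3, n_matching=36)
        from carefuse.text_index import build_index, parse_query
        idx = build_index(docs)
        page = idx.search(parse_query("blod OR bt", doc_type="andre"))
        assert page.total == 36

    def test_status_profile_counts(self, pack_no):
        docs = generate_status_profile_corpus(
            "1", {"negative": 7, "uncertain": 9, "former": 1})
        annotated = [annotate_document(d, pack_no) for d in docs]
        got = [s for d in annotated
               for s in d.extracted.get("smoking_status_value", [])]
        assert sorted(got) == sorted(["negative"] * 7 + ["uncertain"] * 9
                                     + ["former"])


class TestEvaluation:
    def test_perfect_annotation_scores_one(self, pack_no):
        docs, truth = generate_notes(SimConfig(seed=5, n_patients=1,
                                               notes_per_patient=(5, 10)))
        table = evaluate_extraction(annotate_corpus(docs, pack_no), truth)
        active = table[(table.tp + table.fn) > 0]
        assert (active.precision == 1.0).all() and (active.recall == 1.0).all()

    def test_empty_annotator_has_zero_recall_and_nan_precision(self):
        docs = [DocumentRecord("d1", "1", "andre", "2015-01-01T00:00:00",
                               "Puls: 72.")]
        truth = GroundTruth(vitals={"d1": [("pulse", 72.0)]},
                            statuses={"d1": []})
        table = evaluate_extraction(docs, truth)  # no annotations at all
        row = table.loc["pulse"]
        assert row.recall == 0.0
        assert row.precision != row.precision  # NaN -> reported as n/a

    def test_hand_scored_fixture(self, pack_no):
        """Five documents scored by hand: 3 pulse tp, 1 fn, 1 status tp."""
        docs = [
            DocumentRecord("d1", "1", "a", "2015-01-01T00:00:00", "Puls: 70."),
            DocumentRecord("d2", "1", "a", "2015-01-01T00:00:00", "puls 80"),
            DocumentRecord("d3", "1", "a", "2015-01-01T00:00:00", "Puls: 90."),
            DocumentRecord("d4", "1", "a", "2015-01-01T00:00:00",
                           "pXls 99"),  # corrupted keyword: planted but lost
            DocumentRecord("d5", "1", "a", "2015-01-01T00:00:00",
                           "Røyker ikke."),
        ]
        truth = GroundTruth(
            vitals={"d1": [("pulse", 70.0)], "d2": [("pulse", 80.0)],
                    "d3": [("pulse", 90.0)], "d4": [("pulse", 99.0)],
                    "d5": []},
            statuses={"d1": [], "d2": [], "d3": [], "d4": [],
                      "d5": [("smoking", "negative")]})
        table = evaluate_extraction(annotate_corpus(docs, pack_no), truth)
        pulse = table.loc["pulse"]
        assert (pulse.tp, pulse.fp, pulse.fn) == (3, 0, 1)
        assert pulse.precision == 1.0 and pulse.recall == 0.75
        neg = table.loc["smoking:negative"]
        assert (neg.tp, neg.fp, neg.fn) == (1, 0, 0)

    def test_doc_id_mismatch_raises_alignment_error(self):
        docs = [DocumentRecord("other", "1", "a", "2015-01-01T00:00:00", "x")]
        truth = GroundTruth(vitals={"d1": []}, statuses={"d1": []})
        with pytest.raises(AlignmentError):
            evaluate_extraction(docs, truth)


class TestRunDirectory:
    def test_write_run_produces_manifest_and_files(self, tmp_path):
        cfg = SimConfig(seed=6, n_patients=2, notes_per_patient=(2, 5))
        run = write_run(cfg, tmp_path / "run")
        manifest = json.loads((run / "manifest.json").read_text())
        assert manifest["seed"] == 6
        for name in manifest["files"]:
            assert (run / name).exists()

    def test_rerun_same_seed_gives_identical_manifest(self, tmp_path):
        cfg = SimConfig(seed=6, n_patients=2, notes_per_patient=(2, 5))
        r1 = write_run(cfg, tmp_path / "a")
        r2 = write_run(cfg, tmp_path / "b")
        assert (r1 / "manifest.json").read_text() == \
            (r2 / "manifest.json").read_text()
        assert sha(r1 / "notes.jsonl") == sha(r2 / "notes.jsonl")
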
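import json
from datetime import date

import pytest
from hypothesis import given, settings, strategies as st

from phenoval import CohortSpec, Coding, generate, read_bundle, read_bundle_dir, write_bundle
from phenoval.ehr_model import (ConceptRole, ValueSet, ValueSetEntry,
                                load_valuesets, normalize_name)
from phenoval.errors import ConfigError, DataError

from _oracles import vs_match


def _write(path, lines):
    path.write_text("".join(line + "\n" for line in lines))


class TestReadBundle:
    def test_empty_patient_file_gives_empty_bundle(self, tmp_path):
        _write(tmp_path / "Patient.ndjson", [])
        bundle = read_bundle({"Patient": tmp_path / "Patient.ndjson"})
        assert bundle.patients == [] and not bundle.rejects

    def test_missing_patient_file_is_fatal(self, tmp_path):
        with pytest.raises(DataError):
            read_bundle({"Patient": tmp_path / "nope.ndjson"})
        with pytest.raises(DataError):
            read_bundle({"Condition": tmp_path / "Condition.ndjson"})

    def test_malformed_line_is_rejected_not_dropped(self, tmp_path):
        bundle, labels = generate(CohortSpec(n_patients=3, seed=5))
        out = tmp_path / "b"
        write_bundle(bundle, out)
        lines = (out / "Patient.ndjson").read_text().splitlines()
        assert len(lines) == 3
        _write(out / "Patient.ndjson", lines[:2] + ["{not json"])
        reread = read_bundle_dir(out)
        assert len(reread.patients) == 2
        assert len([r for r in reread.rejects if "malformed" in r.reason]) == 1

    def test_unknown_resource_type_line_rejected_with_reason(self, tmp_path):
        bundle, _ = generate(CohortSpec(n_patients=2, seed=5))
        out = tmp_path / "b"
        write_bundle(bundle, out)
        stray = json.dumps({"resourceType": "Basic", "id": "X1"})
        with (out / "Patient.ndjson").open("a") as fh:
            fh.write(stray + "\n")
        reread = read_bundle_dir(out)
        assert any("resourceType" in r.reason for r in reread.rejects)

    def test_orphan_clinical_records_go_to_rejects(self, tmp_path):
        bundle, _ = generate(CohortSpec(n_patients=2, seed=7))
        out = tmp_path / "b"
        write_bundle(bundle, out)
        cond = {"resourceType": "Condition", "id": "C999999",
                "subject": {"reference": "Patient/P999999"},
                "code": {"coding": [{"system": "s", "code": "c"}]},
                "onsetDateTime": "2021-01-01"}
        with (out / "Condition.ndjson").open("a") as fh:
            fh.write(json.dumps(cond) + "\n")
        reread = read_bundle_dir(out)
        assert all(c.patient_id in reread.patient_ids() for c in reread.conditions)
        assert any("unknown patient_id" in r.reason for r in reread.rejects)

    def test_reject_accounting_conserves_line_counts(self, tmp_path):
        bundle, _ = generate(CohortSpec(n_patients=10, n_true_cases=2, seed=11))
        out = tmp_path / "b"
        write_bundle(bundle, out)
        lines = (out / "Observation.ndjson").read_text().splitlines()
        _write(out / "Observation.ndjson", lines + ["oops", '{"resourceType":"Patient","id":"Z"}'])
        reread = read_bundle_dir(out)
        n_input = sum(len(p.read_text().splitlines()) for p in out.glob("*.ndjson")
                      if p.stem != "truth_labels")
        n_accepted = (len(reread.patients) + len(reread.encounters) + len(reread.conditions)
                      + len(reread.immunizations) + len(reread.observations)
                      + sum(len(v) for v in reread.passthrough.values()))
        assert n_accepted + len(reread.rejects) == n_input


class TestRoundTrip:
    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), n=st.integers(1, 25))
    def test_generator_output_round_trips(self, tmp_path_factory, seed, n):
        """read(write(b)) reproduces every typed field and pass-through byte."""
        spec = CohortSpec(n_patients=n, n_true_cases=min(2, n), seed=seed)
        bundle, _ = generate(spec)
        out = tmp_path_factory.mktemp("rt")
        write_bundle(bundle, out)
        reread = read_bundle_dir(out)
        assert not reread.rejects
        assert reread.sorted_copy() == bundle.sorted_copy()

    def test_single_patient_writes_single_line(self, tmp_path):
        bundle, _ = generate(CohortSpec(n_patients=1, seed=3))
        write_bundle(bundle, tmp_path)
        assert len((tmp_path / "Patient.ndjson").read_text().splitlines()) == 1

    def test_passthrough_preserved_verbatim(self, tmp_path):
        bundle, _ = generate(CohortSpec(n_patients=5, n_true_cases=2, seed=9))
        assert bundle.passthrough.get("DocumentReference")
        write_bundle(bundle, tmp_path)
        on_disk = (tmp_path / "DocumentReference.ndjson").read_text().splitlines()
        assert sorted(on_disk) == sorted(bundle.passthrough["DocumentReference"])


class TestValueSets:
    def test_default_config_covers_all_three_roles(self, valuesets):
        assert {vs.role for vs in valuesets} == set(ConceptRole)

    def test_duplicate_entry_error_names_the_duplicate(self):
        with pytest.raises(ConfigError, match=r"I40\.9"):
            ValueSet("dupes", ConceptRole.target_diagnosis,
                     [ValueSetEntry("ICD-10-CM", "I40.9"),
                      ValueSetEntry("ICD-10-CM", "I40.9")])

    def test_unknown_role_error_names_the_set(self, tmp_path):
        cfg = tmp_path / "vs.yaml"
        cfg.write_text(
            "valuesets:\n  - name: broken\n    role: nonsense\n"
            "    entries: [{system: s, code: c}]\n")
        with pytest.raises(ConfigError, match="broken"):
            load_valuesets(cfg)

    def test_missing_role_in_config_is_fatal(self, tmp_path):
        cfg = tmp_path / "vs.yaml"
        cfg.write_text(
            "valuesets:\n  - name: only-dx\n    role: target_diagnosis\n"
            "    entries: [{system: s, code: c}]\n")
        with pytest.raises(ConfigError, match="missing"):
            load_valuesets(cfg)

    def test_csv_and_yaml_loaders_agree(self, tmp_path):
        rows = ["name,role,system,code,prefix_flag,description",
                "dx,target_diagnosis,sysA,I40,true,",
                "dx,target_diagnosis,sysA,I51.4,,",
                "ev,supporting_evidence,sysB,6598-7,,",
                "vax,exposure_vaccine,sysC,207,,"]
        csv_path = tmp_path / "vs.csv"
        csv_path.write_text("\n".join(rows) + "\n")
        sets = {vs.name: vs for vs in load_valuesets(csv_path)}
        assert sets["dx"].entries[0].prefix is True
        assert sets["dx"].contains(Coding("sysA", "I40.9"))
        assert not sets["dx"].contains(Coding("sysA", "I41"))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(codes=st.lists(st.text(alphabet="IJK0123456789.", min_size=1, max_size=6),
                          min_size=1, max_size=8, unique=True),
           prefixes=st.lists(st.booleans(), min_size=8, max_size=8),
           probe=st.text(alphabet="IJK0123456789.", min_size=1, max_size=6),
           probe_system=st.sampled_from(["sysA", "sysB"]))
    def test_membership_matches_linear_scan_oracle(self, codes, prefixes, probe, probe_system):
        """A coding matches iff (system, code) match exactly, or by declared prefix."""
        vs = ValueSet("t", ConceptRole.target_diagnosis,
                      [ValueSetEntry("sysA", c, prefix=p) for c, p in zip(codes, prefixes)])
        coding = Coding(probe_system, probe)
        assert vs.contains(coding) == vs_match([vs], coding)


def test_name_normalization_is_casefold_punct_and_space_insensitive():
    assert normalize_name("  O'Brien,  Mary-Jane ") == normalize_name("o brien mary jane")
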
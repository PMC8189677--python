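"""VDF engine: content identity, blocking reads, caching, eviction."""

import threading

import pytest

from provfs import VDFEngine, VDFTaskError
from provfs.config import CacheConfig, Config, VDFSpec
from provfs.synthetic import gen_vdf_fixtures, materialize_tree

from conftest import direct_vdf_output


def make_engine(tmp_path, block_size=4096, memory_limit=16 * 4096, rules=None):
    tree, config = gen_vdf_fixtures(seed=0)
    root = tmp_path / "root"
    root.mkdir(exist_ok=True)
    materialize_tree(tree, root)
    cfg = Config(
        vdf_rules=rules or config.vdf_rules,
        cache=CacheConfig(block_size=block_size, memory_limit=memory_limit),
    )
    return VDFEngine(cfg, root, disk_tier=tmp_path / "cache"), tree, root


class TestResolution:
    def test_resolves_existing_source(self, tmp_path):
        engine, _, _ = make_engine(tmp_path)
        spec, src = engine.resolve_virtual("reads0.fastq.fasta")
        assert spec.name == "fastq_to_fasta" and src == "reads0.fastq"

    def test_no_source_no_resolution(self, tmp_path):
        engine, _, _ = make_engine(tmp_path)
        assert engine.resolve_virtual("missing.fastq.fasta") is None
        assert engine.resolve_virtual("reads0.fasta") is None

    def test_chained_rules_resolve_through_virtual_source(self, tmp_path):
        rules = [
            VDFSpec(name="x_to_a", source_pattern="*.x", extension=".a",
                    command_template="cat {source}"),
            VDFSpec(name="a_to_b", source_pattern="*.a", extension=".b",
                    command_template="tr 'a-z' 'A-Z' < {source}"),
        ]
        engine, _, root = make_engine(tmp_path, rules=rules)
        (root / "f.x").write_bytes(b"abc\n")
        spec, src = engine.resolve_virtual("f.x.a.b")
        assert spec.name == "a_to_b" and src == "f.x.a"
        assert engine.read("f.x.a.b") == b"ABC\n"


class TestContentIdentity:
    @pytest.mark.parametrize("block_size", [64, 4096])
    def test_all_rules_match_direct_command_output(self, tmp_path, block_size):
        engine, tree, root = make_engine(tmp_path, block_size=block_size)
        cases = [
            ("reads0.fastq.fasta", "reads0.fastq"),
            ("empty.fastq.fasta", "empty.fastq"),
            ("abundance.csv.col1", "abundance.csv"),
            ("notes.txt.sorted", "notes.txt"),
        ]
        for vpath, src in cases:
            spec, _ = engine.resolve_virtual(vpath)
            direct = direct_vdf_output(spec, root / src, tmp_path)
            assert engine.read(vpath) == direct, vpath

    def test_empty_source_empty_vdf(self, tmp_path):
        engine, _, _ = make_engine(tmp_path)
        assert engine.read("empty.fastq.fasta") == b""
        mat = engine.materialize("empty.fastq.fasta")
        assert mat.cache.final_length == 0

    def test_read_past_end_returns_empty(self, tmp_path):
        engine, _, _ = make_engine(tmp_path)
        mat = engine.materialize("abundance.csv.col1")
        full = mat.read_all()
        assert mat.read_block(10_000) == b""
        assert mat.read(len(full) + 5, 100) == b""

    def test_byte_range_reads_consistent(self, tmp_path):
        engine, _, _ = make_engine(tmp_path, block_size=16)
        mat = engine.materialize("reads0.fastq.fasta")
        full = mat.read_all()
        assert mat.read(3, 40) == full[3:43]
        assert mat.read(0, 10**6) == full


class TestSingleExecution:
    def test_command_runs_once_for_many_reads(self, tmp_path):
        engine, _, _ = make_engine(tmp_path)
        for _ in range(5):
            engine.read("reads1.fastq.fasta")
        assert engine.task_launches() == 1

    def test_concurrent_readers_one_task_identical_bytes(self, tmp_path):
        engine, _, root = make_engine(tmp_path)
        big = root / "big.txt"
        big.write_bytes(b"".join(f"row{i % 13}\n".encode() for i in range(30000)))
        results, errs = [], []

        def reader():
            try:
                results.append(engine.read("big.txt.sorted"))
            except Exception as exc:  # pragma: no cover
                errs.append(exc)

        threads = [threading.Thread(target=reader) for _ in range(4)]
        for t in threads:
            t.start()
        for t in threads:
            t.join()
        assert not errs
        assert len(results) == 4 and len(set(results)) == 1
        assert results[0] == b"".join(sorted(big.read_bytes().splitlines(keepends=True)))
        assert engine.task_launches() == 1

    def test_source_modification_triggers_fresh_task(self, tmp_path):
        engine, tree, root = make_engine(tmp_path)
        first = engine.read("reads2.fastq.fasta")
        assert engine.task_launches() == 1
        (root / "reads2.fastq").write_bytes(tree["reads0.fastq"])
        second = engine.read("reads2.fastq.fasta")
        assert engine.task_launches() == 2
        assert first != second


class TestEviction:
    def test_spill_preserves_content_identity(self, tmp_path):
        # memory holds only 2 blocks: most blocks must spill to disk
        engine, _, root = make_engine(tmp_path, block_size=1024, memory_limit=2048)
        big = root / "big.txt"
        big.write_bytes(b"".join(f"z{i:06d}\n".encode() for i in range(5000)))
        got = engine.read("big.txt.sorted")
        mat = engine.materialize("big.txt.sorted")
        assert mat.cache.spill_count > 0
        assert got == b"".join(sorted(big.read_bytes().splitlines(keepends=True)))

    def test_memory_occupancy_bounded_after_eviction(self, tmp_path):
        engine, _, root = make_engine(tmp_path, block_size=1024, memory_limit=4096)
        (root / "big.txt").write_bytes(b"x\n" * 20000)
        mat = engine.materialize("big.txt.sorted")
        mat.read_all()
        assert mat.cache.memory_bytes() <= 4096

    def test_under_limit_no_spill(self, tmp_path):
        engine, _, _ = make_engine(tmp_path, block_size=4096, memory_limit=1 << 20)
        engine.read("abundance.csv.col1")
        mat = engine.materialize("abundance.csv.col1")
        assert mat.cache.spill_count == 0

    def test_spilled_block_promoted_back_unchanged(self, tmp_path):
        engine, _, root = make_engine(tmp_path, block_size=512, memory_limit=1024)
        (root / "big.txt").write_bytes(b"".join(f"q{i:05d}\n".encode() for i in range(2000)))
        mat = engine.materialize("big.txt.sorted")
        full = mat.read_all()
        # block 0 was produced first and must have spilled; re-read promotes it
        again = mat.read_block(0)
        assert again == full[:512]
        assert mat.cache.memory_bytes() <= 1024


class TestFailures:
    def test_failing_command_surfaces_to_readers(self, tmp_path):
        rules = [VDFSpec(name="boom", source_pattern="*.txt", extension=".boom",
                         command_template="cat {source}; exit 3")]
        engine, _, root = make_engine(tmp_path, rules=rules)
        (root / "n.txt").write_bytes(b"data\n" * 10_000)
        mat = engine.materialize("n.txt.boom")
        with pytest.raises(VDFTaskError):
            # ask for a block beyond what the failed task produced
            mat.read_block(10**6)


class TestCopyOut:
    def test_copy_out_matches_direct_and_reuses_cache(self, vdf_mount, tmp_path):
        mount, tree, root = vdf_mount
        dest1 = tmp_path / "o1.fasta"
        dest2 = tmp_path / "o2.fasta"
        mount.copy_out("reads0.fastq.fasta", dest1)
        launches = mount.engine.task_launches()
        mount.copy_out("reads0.fastq.fasta", dest2)
        assert mount.engine.task_launches() == launches  # cache reuse
        spec, _ = mount.engine.resolve_virtual("reads0.fastq.fasta")
        direct = direct_vdf_output(spec, root / "reads0.fastq", tmp_path)
        assert dest1.read_bytes() == dest2.read_bytes() == direct

    def test_vdf_visible_as_regular_file(self, vdf_mount):
        mount, _, _ = vdf_mount
        st = mount.stat("reads0.fastq.fasta")
        assert st["virtual"] and st["st_size"] == 0  # unmaterialized: size 0
        data = mount.read_file("reads0.fastq.fasta")
        assert mount.stat("reads0.fastq.fasta")["st_size"] == len(data)

    def test_vdf_lineage_recorded(self, vdf_mount):
        from provfs import trace

        mount, _, _ = vdf_mount
        content = mount.read_file("abundance.csv.col1")
        mount.write_file("derived.txt", content)
        g = trace(mount.store.current_version("derived.txt").file_key, mount.store)
        paths = {mount.store.get_file(f).path for f in g.file_nodes}
        assert {"derived.txt", "abundance.csv.col1", "abundance.csv"} <= paths
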
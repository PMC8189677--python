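"""Passthrough fidelity, routing, listing and caller capture."""

import hashlib
import os
import random

import pytest

from provfs import Mount, SyscallEvent, capture_caller, route_operation
from provfs.config import Config, VDFSpec
from provfs.procinfo import checksum_file
from provfs.store import READ, WRITE
from provfs.vfs import AccessError, normalize_path

FASTA_RULE = VDFSpec(
    name="fq2fa", source_pattern="*.fastq", extension=".fasta",
    command_template="awk 'NR%4==1{sub(/^@/,\">\");print} NR%4==2{print}' {source}",
)


@pytest.fixture
def mount(tmp_path):
    root = tmp_path / "root"
    root.mkdir()
    m = Mount(root, Config(vdf_rules=[FASTA_RULE]), disk_tier=tmp_path / "cache")
    yield m
    m.store.close()


class TestRouting:
    def ev(self, path):
        return SyscallEvent(op_kind="open", path=path, caller_pid=os.getpid())

    def test_real_file_routes_real(self, mount):
        mount.write_file("reads.fastq", b"@r\nAC\n+\nII\n")
        assert route_operation(self.ev("reads.fastq"), mount.ctx, mount.engine) == "real"

    def test_vdf_name_with_source_routes_virtual(self, mount):
        mount.write_file("reads.fastq", b"@r\nAC\n+\nII\n")
        assert (
            route_operation(self.ev("reads.fastq.fasta"), mount.ctx, mount.engine)
            == "virtual"
        )

    def test_vdf_name_without_source_falls_through_to_real(self, mount):
        assert (
            route_operation(self.ev("ghost.fastq.fasta"), mount.ctx, mount.engine)
            == "real"
        )
        with pytest.raises(FileNotFoundError):
            mount.open("ghost.fastq.fasta")

    def test_escaping_path_rejected(self, mount):
        with pytest.raises(AccessError):
            normalize_path("../outside")
        with pytest.raises(AccessError):
            mount.open("a/../../etc/passwd")


class TestListing:
    def test_virtual_entries_appended(self, mount):
        mount.write_file("a.fastq", b"@r\nA\n+\nI\n")
        mount.write_file("b.txt", b"x")
        assert mount.readdir("") == ["a.fastq", "a.fastq.fasta", "b.txt"]

    def test_empty_dir_empty_listing(self, mount):
        mount.mkdir("sub")
        assert mount.readdir("sub") == []

    def test_real_file_shadows_virtual_entry(self, mount):
        mount.write_file("a.fastq", b"@r\nA\n+\nI\n")
        mount.write_file("a.fastq.fasta", b"already real")
        listing = mount.readdir("")
        assert listing.count("a.fastq.fasta") == 1
        # and opening it returns the real content
        assert mount.read_file("a.fastq.fasta") == b"already real"


class TestPassthrough:
    def test_write_read_back_identical(self, mount):
        payload = os.urandom(1 << 20)
        mount.write_file("blob.bin", payload)
        assert mount.read_file("blob.bin") == payload
        direct = (
            hashlib.sha256(open(os.path.join(mount.source_root, "blob.bin"), "rb").read())
            .hexdigest()
        )
        assert direct == hashlib.sha256(payload).hexdigest()

    def test_stat_matches_direct(self, mount):
        mount.write_file("f.txt", b"hello")
        st = mount.stat("f.txt")
        direct = os.stat(os.path.join(mount.source_root, "f.txt"))
        assert st.st_size == direct.st_size and st.st_mtime == direct.st_mtime

    def test_unlink_removes_real_file(self, mount):
        mount.write_file("f.txt", b"x")
        mount.unlink("f.txt")
        with pytest.raises(FileNotFoundError):
            mount.stat("f.txt")
        assert not os.path.exists(os.path.join(mount.source_root, "f.txt"))

    def test_mixed_workload_tree_identical_to_direct(self, tmp_path):
        """The same scripted op sequence against the mount and a plain
        directory must leave byte-identical trees."""
        rng = random.Random(42)
        script = []
        names = [f"f{i}.dat" for i in range(12)]
        for _ in range(800):
            op = rng.choice(["write", "append", "read", "rename", "unlink"])
            script.append((op, rng.choice(names), rng.choice(names),
                           rng.randbytes(rng.randint(1, 512))))

        def apply_direct(root, ops):
            for op, a, b, data in ops:
                pa, pb = os.path.join(root, a), os.path.join(root, b)
                try:
                    if op == "write":
                        open(pa, "wb").write(data)
                    elif op == "append":
                        open(pa, "ab").write(data)
                    elif op == "read":
                        open(pa, "rb").read()
                    elif op == "rename":
                        os.rename(pa, pb)
                    elif op == "unlink":
                        os.remove(pa)
                except FileNotFoundError:
                    pass

        def apply_mount(m, ops):
            for op, a, b, data in ops:
                try:
                    if op == "write":
                        m.write_file(a, data)
                    elif op == "append":
                        h = m.open(a, "a")
                        m.write(h, data)
                        m.close(h)
                    elif op == "read":
                        m.read_file(a)
                    elif op == "rename":
                        m.rename(a, b)
                    elif op == "unlink":
                        m.unlink(a)
                except FileNotFoundError:
                    pass

        direct_root = tmp_path / "direct"
        direct_root.mkdir()
        apply_direct(direct_root, script)
        mnt_root = tmp_path / "mounted"
        mnt_root.mkdir()
        m = Mount(mnt_root)
        apply_mount(m, script)

        def tree(root):
            out = {}
            for dirpath, _, files in os.walk(root):
                for f in files:
                    p = os.path.join(dirpath, f)
                    out[os.path.relpath(p, root)] = hashlib.sha256(
                        open(p, "rb").read()
                    ).hexdigest()
            return out

        assert tree(mnt_root) == tree(direct_root)
        m.store.close()


class TestRecording:
    def test_every_data_op_recorded_once(self, mount):
        mount.write_file("f.txt", b"abc")  # create + write + close
        mount.read_file("f.txt")  # open + read + close
        store = mount.store
        fv = store.current_version("f.txt")
        writes = store.query_writes(fv.file_key)
        assert sum(e.count for _, e in writes if e.op_kind == "write") == 1
        assert store.primitive_op_count((READ, WRITE)) == 2

    def test_reader_then_writer_creates_new_version(self, mount):
        mount.write_file("f.txt", b"v0")
        mount.read_file("f.txt")
        v0 = mount.store.current_version("f.txt")
        mount.write_file("f.txt", b"v1")
        v1 = mount.store.current_version("f.txt")
        assert v1.version_no == v0.version_no + 1
        assert v0.content_checksum == hashlib.sha256(b"v0").hexdigest()
        assert v1.content_checksum == hashlib.sha256(b"v1").hexdigest()

    def test_content_checksum_set_at_writer_close(self, mount):
        h = mount.open("f.txt", "w")
        mount.write(h, b"part1")
        assert mount.store.current_version("f.txt").content_checksum is None
        mount.close(h)
        assert mount.store.current_version("f.txt").content_checksum is not None


class TestCallerCapture:
    def test_capture_self_process(self):
        info = capture_caller(os.getpid())
        assert info.pid == os.getpid()
        assert info.cmdline and "python" in os.path.basename(info.cmdline[0]).lower()
        assert info.cwd == os.getcwd()
        assert info.exe_path and info.exe_checksum == checksum_file(info.exe_path)
        # repeated capture of a live process is stable
        assert capture_caller(os.getpid()) == info

    def test_exited_process_marked_unavailable(self):
        import subprocess

        p = subprocess.Popen(["/bin/sh", "-c", "exit 0"])
        p.wait()
        info = capture_caller(p.pid)
        # pid may be reused in principle, but immediately after wait it is gone
        assert info.available is False or info.pid == p.pid

    def test_daemon_self_flagged_and_excluded(self, tmp_path):
        root = tmp_path / "r"
        root.mkdir()
        m = Mount(root, daemon_pid=os.getpid())
        info = capture_caller(os.getpid(), daemon_pid=os.getpid())
        assert info.is_self
        m.write_file("f.txt", b"x")  # caller == daemon: not recorded
        fv = m.store.current_version("f.txt")
        assert fv is not None and m.store.query_writes(fv.file_key) == []
        m.store.close()

    def test_child_process_links_to_parent(self, mount):
        """A captured child's record links to its parent's record."""
        info_parent = capture_caller(os.getpid())
        pk = mount.store.record_caller(info_parent)
        import subprocess

        child = subprocess.Popen(["sleep", "0.5"])
        try:
            info_child = capture_caller(child.pid)
            ck = mount.store.record_caller(info_child)
            assert mount.store.get_process(ck).parent_key == pk
        finally:
            child.terminate()
            child.wait()
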
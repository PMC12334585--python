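# Non-sequential topology templates (edges in temporal order, abstract labels).
#
# Each template is a typed temporal pattern that does NOT form a single walk
# but whose underlying multigraph is weakly connected: it decomposes into two
# or more maximal temporal walks ("processes") sharing at least one node.
# Two-edge shapes are the four possible connected non-walk configurations.
# Three-edge shapes pair a single-edge process with a two-type cycle process
# (the single edge first, the cycle following), plus the directed triangle
# whose three edges are pairwise temporally detached.
#
# Kept as data, not code, so the schematics can be corrected without touching
# the classifier.
nonsequential:
  - name: Ring_n
    edges: ["A>B", "A>B"]          # the same transition repeated
  - name: Chain_n1
    edges: ["A>B", "A>C"]          # two processes sharing their source
  - name: Chain_n2
    edges: ["A>B", "C>B"]          # two processes sharing their target
  - name: Chain_n3
    edges: ["A>B", "C>A"]          # later process ends where the earlier began
  - name: Triple_line_n1
    edges: ["A>B", "A>B", "B>A"]   # single edge, then cycle between the two types
  - name: Triple_line_n2
    edges: ["A>B", "B>A", "B>A"]   # cycle between two types, then single edge
  - name: Star_pos_n1
    edges: ["A>B", "C>B", "B>C"]   # branch into shared type B, then cycle B<->C
  - name: Star_pos_n2
    edges: ["A>B", "A>C", "C>A"]   # branch out of shared type A, then cycle A<->C
  - name: Triad_n
    edges: ["A>B", "C>A", "B>C"]   # directed triangle, three detached edges
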
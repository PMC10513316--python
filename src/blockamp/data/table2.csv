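sample_id,sanger,new_method,ratio_percent
1-1,+,+,n.t.
1-2,+,+,n.t.
1-3,+,+,n.t.
1-4,-,+,0.1
1-5,+,+,n.t.
1-6,-,+,0.4
1-7,+,+,n.t.
1-8,+,+,n.t.
1-9,+,+,n.t.
1-10,+,+,n.t.
1-11,-,-,0.0
1-12,-,-,0.0
1-13,+,+,n.t.
1-14,-,-,0.0
1-15,+,+,14.3
1-16,-,-,n.t.
1-17,+,+,49.6
1-18,+,+,n.t.
1-19,-,-,n.t.
1-20,-,+,1.2
1-21,+,+,n.t.
1-22,-,-,n.t.
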
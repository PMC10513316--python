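sample_id,sanger,new_method,ratio_percent
2-1,-,-,n.t.
2-2,-,-,0.0
2-3,+,+,43.8
2-4,-,-,n.t.
2-5,-,-,n.t.
2-6,-,-,n.t.
2-7,-,-,n.t.
2-8,+,+,18.9
2-9,+,+,37.6
2-10,-,-,n.t.
2-11,-,+,1.4
2-12,-,-,0.0
2-13,-,-,n.t.
2-14,-,-,n.t.
2-15,-,-,n.t.
2-16,-,-,n.t.
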
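statistic	value	oracle
gamma3:gamma	-0.346410161514	direct formula arithmetic (T=5, S_2=2)
harmonic5:gamma	0	algebraic identity: g_k = c/k makes S_i linear
harmonic10:gamma	0	algebraic identity: g_k = c/k makes S_i linear
harmonic50:gamma	0	algebraic identity: g_k = c/k makes S_i linear
study122:root_age	16.2	rescaling target
study90:n_branching_times	89	n - 1 count
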